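"""Marker discovery: beta values, QC, Mann-Whitney, BH, selection, ranking."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletorigin import synthetic_data as sd
from isletorigin.array_dm import (
    BetaMatrix,
    bh_adjust,
    compute_beta,
    differential_methylation,
    mann_whitney_u,
    qc_filter,
    rank_top,
    read_beta_matrix,
    select_markers,
)


def make_matrix(beta, groups, cross=None, snp=None, detection=None):
    n_probes, n_samples = np.asarray(beta).shape
    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{i:03d}" for i in range(n_probes)],
            "chrom": "chr1",
            "pos": np.arange(1, n_probes + 1),
            "cross_reactive": cross if cross is not None else np.zeros(n_probes, bool),
            "snp": snp if snp is not None else np.zeros(n_probes, bool),
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n_samples)], "group": groups}
    )
    det = detection if detection is not None else np.zeros((n_probes, n_samples))
    return BetaMatrix(probes=probes, samples=samples, beta=np.asarray(beta, float),
                      detection_p=det)


class TestComputeBeta:
    @pytest.mark.parametrize("M, U, expected", [(600, 400, 0.6), (0, 500, 0.0),
                                                (250, 250, 0.5)])
    def test_examples(self, M, U, expected):
        assert compute_beta(M, U) == pytest.approx(expected)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_beta(0, 0)

    def test_negative_intensity_raises(self):
        with pytest.raises(ValueError):
            compute_beta(-1, 5)


class TestQcFilter:
    def test_identity_when_clean(self):
        bm = make_matrix(np.full((4, 4), 0.5), ["islet"] * 2 + ["control"] * 2)
        out = qc_filter(bm)
        assert out.n_probes == 4

    def test_all_flagged_raises(self):
        bm = make_matrix(np.full((3, 4), 0.5), ["islet"] * 2 + ["control"] * 2,
                         snp=np.ones(3, bool))
        with pytest.raises(ValueError, match="no probes"):
            qc_filter(bm)

    def test_counting_under_stated_rules(self):
        """10 probes: 2 cross-reactive + 1 with a failing detection p -> 7 kept."""
        cross = np.zeros(10, bool)
        cross[[0, 1]] = True
        det = np.zeros((10, 4))
        det[5, 2] = 0.06
        bm = make_matrix(np.full((10, 4), 0.5), ["islet"] * 2 + ["control"] * 2,
                         cross=cross, detection=det)
        out = qc_filter(bm, detection_threshold=0.05)
        assert out.n_probes == 7
        assert "cg005" not in set(out.probes["probe_id"])

    def test_majority_rule_keeps_single_failure(self):
        det = np.zeros((2, 4))
        det[0, 0] = 0.06
        bm = make_matrix(np.full((2, 4), 0.5), ["islet"] * 2 + ["control"] * 2,
                         detection=det)
        assert qc_filter(bm, rule="majority").n_probes == 2
        assert qc_filter(bm, rule="any").n_probes == 1


def exact_mw_two_sided(x, y):
    """Enumeration oracle: exact two-sided Mann-Whitney p over all rank splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    order = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    ranks = np.array([order[v] for v in pooled], dtype=float)

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    us = [u_of(c) for c in combinations(range(len(pooled)), n1)]
    us = np.array(us)
    total = len(us)
    p = 2.0 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_spec_toy_exact(self):
        """[0.1, 0.2] vs [0.8, 0.9]: U = 0 and exact two-sided p = 2/6."""
        u, p = mann_whitney_u([0.1, 0.2], [0.8, 0.9])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 6.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_path_matches_enumeration(self, seed):
        """Exact p equals brute-force enumeration for combined n <= 8 (tie-free)."""
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 9 - n1))
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        x, y = vals[:n1], vals[n1:]
        u_ref, p_ref = exact_mw_two_sided(x, y)
        u, p = mann_whitney_u(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_constant_input_p_one(self):
        u, p = mann_whitney_u([0.5, 0.5], [0.5, 0.5, 0.5])
        assert p == 1.0

    def test_large_n_uses_tie_corrected_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.choice([0.1, 0.2, 0.3], size=30)
        y = rng.choice([0.2, 0.3, 0.4], size=30)
        _, p = mann_whitney_u(x, y)
        assert 0.0 < p <= 1.0


def bh_stepup_oracle(p):
    """Direct evaluation of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m / (i + 1) * p[order[i]])
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.001, 0.01, 0.02, 0.8]),
            [0.004, 0.02, 0.0266666667, 0.8],
            rtol=1e-6,
        )

    @pytest.mark.parametrize("p, expected", [([0.3], [0.3]),
                                             ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])])
    def test_degenerate_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_stepup_definition(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_stepup_oracle(p), rtol=1e-8, atol=1e-12)
        # monotone nondecreasing in sorted-p order, never below raw p rank-wise
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-9)
        assert np.all(q <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDifferentialMethylation:
    def test_null_probe_not_selected(self):
        beta = np.vstack([np.full(6, 0.4), [0.1, 0.15, 0.12, 0.85, 0.9, 0.88]])
        bm = make_matrix(beta, ["islet"] * 3 + ["control"] * 3)
        rec = differential_methylation(bm)
        const = rec.set_index("probe_id").loc["cg000"]
        assert const["delta_beta"] == 0.0
        assert const["status"] == "not_selected"
        assert const["p_value"] == 1.0

    def test_recovers_spiked_markers(self, small_beta_matrix):
        bm, truth = small_beta_matrix
        rec = differential_methylation(qc_filter(bm))
        merged = rec.merge(truth, on="probe_id")
        true_rows = merged.loc[merged["true_dm"]]
        sel = true_rows["status"] != "not_selected"
        assert sel.mean() >= 0.9
        # directions agree with the generator truth
        hyper = true_rows.loc[true_rows["direction"] == "hyper", "delta_beta"]
        hypo = true_rows.loc[true_rows["direction"] == "hypo", "delta_beta"]
        assert (hyper > 0).all() and (hypo < 0).all()

    def test_requires_two_per_group(self):
        bm = make_matrix(np.full((2, 3), 0.5), ["islet", "control", "control"])
        with pytest.raises(ValueError, match="2 samples"):
            differential_methylation(bm)


class TestSelectAndRank:
    @staticmethod
    def records(rows):
        df = pd.DataFrame(rows)
        df["chrom"] = "chr1"
        df["pos"] = np.arange(len(df)) + 1
        return df

    def test_selection_rule(self):
        df = self.records(
            [
                {"probe_id": "a", "delta_beta": 0.6, "q_value": 1e-4},
                {"probe_id": "b", "delta_beta": -0.7, "q_value": 1e-5},
                {"probe_id": "c", "delta_beta": 0.6, "q_value": 0.01},
                {"probe_id": "d", "delta_beta": 0.4, "q_value": 1e-9},
            ]
        )
        sel = select_markers(df)
        assert dict(zip(df["probe_id"], df["status"])) == {
            "a": "hypermethylated",
            "b": "hypomethylated",
            "c": "not_selected",
            "d": "not_selected",
        }
        assert sel.n_hyper == 1 and sel.n_hypo == 1

    def test_rank_order_and_tiebreak(self):
        df = self.records(
            [
                {"probe_id": "a", "delta_beta": 0.9, "q_value": 1e-4},
                {"probe_id": "b", "delta_beta": -0.8, "q_value": 1e-4},
                {"probe_id": "c", "delta_beta": 0.8, "q_value": 1e-6},
                {"probe_id": "d", "delta_beta": 0.7, "q_value": 1e-4},
            ]
        )
        select_markers(df)
        top = rank_top(df, 3)
        # |0.9| first; |0.8| tie broken by smaller q (c before b)
        assert list(top["probe_id"]) == ["a", "c", "b"]

    def test_k_exceeding_selection_warns(self):
        df = self.records(
            [{"probe_id": "a", "delta_beta": 0.9, "q_value": 1e-4},
             {"probe_id": "b", "delta_beta": 0.1, "q_value": 0.5}]
        )
        select_markers(df)
        with pytest.warns(UserWarning, match="only 1"):
            top = rank_top(df, 10)
        assert len(top) == 1


class TestIO:
    def test_write_read_roundtrip(self, small_beta_matrix, tmp_path):
        bm, _ = small_beta_matrix
        paths = sd.write_beta_matrix(bm, tmp_path)
        back = read_beta_matrix(paths["beta"], paths["annot"], paths["samples"],
                                paths["detection"])
        np.testing.assert_allclose(back.beta, bm.beta)
        np.testing.assert_allclose(back.detection_p, bm.detection_p)
        assert list(back.samples["group"]) == list(bm.samples["group"])
        assert list(back.probes["cross_reactive"]) == list(bm.probes["cross_reactive"])
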