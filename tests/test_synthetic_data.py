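"""Generator contracts: determinism, distributions, qualitative bounds."""

import math

import numpy as np
import pandas as pd
import pytest

from isletorigin import cohort_stats as cs
from isletorigin import synthetic_data as sd


class TestGenBetaMatrix:
    def test_determinism(self):
        a, ta = sd.gen_beta_matrix(4, 4, 6, 20, 0.5, seed=42)
        b, tb = sd.gen_beta_matrix(4, 4, 6, 20, 0.5, seed=42)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.detection_p, b.detection_p)
        pd.testing.assert_frame_equal(ta, tb)

    def test_no_signal_case(self):
        bm, truth = sd.gen_beta_matrix(4, 4, 0, 30, 0.5, seed=0)
        assert truth["true_dm"].sum() == 0
        assert bm.n_probes == 30

    def test_effect_size_realised(self):
        """Truth-labelled probes differ by ~ the requested effect (64 vs 27)."""
        bm, truth = sd.gen_beta_matrix(64, 27, 200, 200, 0.7, seed=1)
        islet = bm.group_mask("islet")
        diffs = np.abs(
            bm.beta[:, islet].mean(axis=1) - bm.beta[:, ~islet].mean(axis=1)
        )
        mean_diff = diffs[truth["true_dm"].to_numpy()].mean()
        assert abs(mean_diff - 0.7) < 0.05

    @pytest.mark.parametrize("kwargs", [dict(effect=1.5), dict(effect=0.0),
                                        dict(n_islet=1)])
    def test_invalid_parameters(self, kwargs):
        base = dict(n_islet=4, n_control=4, n_true_dm=2, n_null=10, effect=0.5)
        base.update(kwargs)
        with pytest.raises(ValueError):
            sd.gen_beta_matrix(**base, seed=0)


class TestGenTissuePanel:
    def test_default_config_satisfies_reported_bounds(self):
        """Cross-tissue methylation pattern: the complementary INS/CHTOP design."""
        cfg = sd.default_tissue_config()
        for name, prof in cfg.items():
            if not prof.is_pancreas:
                # every non-pancreatic tissue > 50% methylated at INS
                assert prof.means["u_INS"] < 0.5, name
        for name in ("adipose", "skin"):
            meth = 1 - cfg[name].means["u_INS"]
            assert 0.55 <= meth <= 0.60, name
        for name in ("skeletal_muscle", "brain", "heart"):
            assert 1 - cfg[name].means["u_CHTOP817"] <= 0.5, name
        beta = cfg["beta_cells"].means
        assert 0.48 <= beta["u_CHTOP817"] <= 0.99
        assert beta["u_INS"] > 0.5
        # islet cells hypomethylated at INS; brain CHTOP-unmethylated but INS-methylated
        assert cfg["alpha_cells"].means["u_INS"] > 0.5
        assert cfg["brain"].means["u_CHTOP817"] >= 0.5
        assert cfg["brain"].means["u_INS"] < 0.5

    def test_sample_means_track_config(self):
        cfg = {"beta_cells": sd.default_tissue_config()["beta_cells"]}
        panel = sd.gen_tissue_panel(cfg, n_per_tissue=400, seed=0)
        for marker in sd.MARKERS:
            assert panel[marker].mean() == pytest.approx(
                cfg["beta_cells"].means[marker], abs=0.02
            )
        assert panel[list(sd.MARKERS)].to_numpy().min() >= 0
        assert panel[list(sd.MARKERS)].to_numpy().max() <= 1

    def test_infinite_concentration_gives_exact_means(self):
        prof = sd.TissueProfile(
            means={m: 0.3 for m in sd.MARKERS}, concentration=1e12, is_pancreas=False
        )
        panel = sd.gen_tissue_panel({"t": prof}, n_per_tissue=5, seed=0)
        assert (panel[list(sd.MARKERS)] == 0.3).all().all()

    def test_determinism_and_labels(self, default_panel):
        again = sd.gen_tissue_panel(seed=1)
        pd.testing.assert_frame_equal(default_panel, again)
        betas = default_panel.loc[default_panel["tissue"] == "beta_cells"]
        assert betas["is_beta"].all() and betas["is_islet"].all() \
            and betas["is_pancreas"].all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd.gen_tissue_panel(n_per_tissue=0)
        with pytest.raises(ValueError, match="concentration"):
            sd.TissueProfile(means={"u_INS": 0.5}, concentration=0.0)
        bad = sd.TissueProfile(means={"u_XXX": 0.5})
        with pytest.raises(ValueError, match="unknown markers"):
            sd.gen_tissue_panel({"t": bad}, n_per_tissue=2, seed=0)


class TestGenDropletWell:
    def test_empty_well_all_double_negative(self):
        well = sd.gen_droplet_well((0.0, 0.0), n_droplets=2000, seed=0)
        assert (well.ch1 < 3000).all() and (well.ch2 < 3000).all()

    def test_negative_fraction_matches_poisson(self):
        """Empirical P(empty) ~ e^(-lambda) within 3 binomial SE at n = 1e5."""
        conc, vol, n = 815.5, 8.5e-4, 100_000
        lam = conc * vol
        well = sd.gen_droplet_well((conc, 0.0), n_droplets=n, droplet_volume=vol, seed=4)
        p_neg = (well.ch1 < 3000).mean()
        expect = math.exp(-lam)
        assert expect == pytest.approx(0.5, abs=0.01)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(p_neg - expect) <= 3 * se

    def test_determinism(self):
        a = sd.gen_droplet_well((100.0, 50.0), n_droplets=1000, seed=9)
        b = sd.gen_droplet_well((100.0, 50.0), n_droplets=1000, seed=9)
        np.testing.assert_array_equal(a.ch1, b.ch1)
        np.testing.assert_array_equal(a.ch2, b.ch2)

    def test_overlapping_clusters_warn(self):
        params = (sd.AmplitudeParams(pos_mean=1500.0), sd.AmplitudeParams())
        with pytest.warns(UserWarning, match="2 sd"):
            sd.gen_droplet_well((100.0, 0.0), n_droplets=100,
                                amplitude_params=params, seed=0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            sd.gen_droplet_well((-1.0, 0.0), n_droplets=10, seed=0)


class TestGenSerumCohorts:
    def test_default_spec_directions(self):
        t1d = sd.default_t1d_cohort_spec()
        assert all(f > 1 for f in t1d.cohorts["T1D"].folds.values())
        assert set(t1d.cohorts["T1D"].folds) == set(sd.SPECIES)
        seps = sd.default_sepsis_cohort_spec()
        assert set(seps.cohorts["sepsis"].folds) == {"m_INS", "m_CHTOP817"}
        ob = sd.default_obesity_cohort_spec()
        for c in ("OB-NGT", "IGT", "T2D-AAb-", "T2D-AAb+"):
            assert "m_CHTOP817" not in ob.cohorts[c].folds

    def test_paper_matched_counts(self):
        df = sd.gen_serum_cohorts(sd.default_t1d_cohort_spec(), seed=0)
        assert df["cohort"].value_counts().to_dict() == {
            "T1D": 43, "FDR": 23, "control": 10
        }
        ob = sd.gen_serum_cohorts(sd.default_obesity_cohort_spec(), seed=0)
        assert ob["cohort"].value_counts().to_dict() == {
            "T2D-AAb-": 34, "lean": 32, "OB-NGT": 31, "IGT": 31, "T2D-AAb+": 22
        }

    def test_elevated_groups_exceed_control_means(self):
        df = sd.gen_serum_cohorts(sd.default_t1d_cohort_spec(), seed=2)
        for sp in sd.SPECIES:
            means = df.groupby("cohort")[sp].mean()
            assert means["T1D"] > means["control"]
            assert means["FDR"] > means["control"]

    def test_null_spec_exchangeable(self):
        """All folds 1: omnibus non-significant in >= 90% of 100 seeds."""
        spec = sd.CohortEffectSpec(
            cohorts={"a": sd.CohortEffect(n=20), "b": sd.CohortEffect(n=20),
                     "c": sd.CohortEffect(n=20)}
        )
        nonsig = 0
        for s in range(100):
            df = sd.gen_serum_cohorts(spec, seed=s)
            groups = [g["u_INS"].to_numpy() for _, g in df.groupby("cohort")]
            _, p = cs.kruskal_wallis(*groups)
            nonsig += p >= 0.05
        assert nonsig >= 90

    def test_negative_fold_rejected(self):
        with pytest.raises(ValueError):
            sd.CohortEffect(n=5, folds={"u_INS": -1.0})

    def test_determinism(self):
        a = sd.gen_serum_cohorts(sd.default_sepsis_cohort_spec(), seed=3)
        b = sd.gen_serum_cohorts(sd.default_sepsis_cohort_spec(), seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestGenBisulfiteReads:
    def test_binomial_sampling_accuracy(self, toy_amplicon):
        reads = sd.gen_bisulfite_reads(toy_amplicon, 0.7, 10_000, seed=0)
        from isletorigin.bisulfite import call_methylation

        table = call_methylation(reads, toy_amplicon)
        se = math.sqrt(0.7 * 0.3 / 10_000)
        assert np.all(np.abs(table["fraction"] - 0.7) <= 3 * se)

    def test_conversion_failure_retains_non_cpg_c(self, toy_amplicon):
        reads = sd.gen_bisulfite_reads(toy_amplicon, 0.0, 4000,
                                       conversion_failure=0.2, seed=1)
        # position 5 is a non-CpG C; it should survive in ~20% of reads
        frac_c = np.mean([r[4] == "C" for r in reads])
        assert frac_c == pytest.approx(0.2, abs=0.03)

    def test_determinism(self, toy_amplicon):
        a = sd.gen_bisulfite_reads(toy_amplicon, 0.5, 50, seed=6)
        b = sd.gen_bisulfite_reads(toy_amplicon, 0.5, 50, seed=6)
        assert a == b
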