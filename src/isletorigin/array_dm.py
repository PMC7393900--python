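"""Differential-methylation marker discovery from methylation-array beta values.

The discovery design compares islet preparations against a panel of non-islet
control tissues on a genome-scale CpG methylation array.  Per probe the
methylation level is summarised by the beta value ``M / (U + M)`` (M, U the
methylated and unmethylated raw intensities).  After QC filtering (detection
p-value, cross-reactive probes, SNP-containing probes), each CpG is tested
with a two-sided Mann-Whitney U test (islet vs control), p-values are
adjusted with the Benjamini-Hochberg step-up procedure, and candidate
markers are those with |delta beta| > 0.5 and q < 0.001 — delta beta being
the islet-minus-control difference of group mean betas.  Positive delta beta
among the survivors means islet-hypermethylated, negative means
islet-hypomethylated.  Top markers are ranked by |delta beta| (ties broken
by ascending q, then probe id).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaMatrix",
    "MarkerSelection",
    "compute_beta",
    "qc_filter",
    "differential_methylation",
    "select_markers",
    "rank_top",
    "bh_adjust",
    "mann_whitney_u",
    "read_beta_matrix",
]

logger = logging.getLogger(__name__)

#: combined sample size at or below which the exact Mann-Whitney null is used
EXACT_MW_MAX_N = 20

ISLET = "islet"
CONTROL = "control"

MARKER_COLUMNS = [
    "probe_id", "chrom", "pos", "mean_islet", "mean_control",
    "delta_beta", "mw_u", "p_value", "q_value", "status",
]

HYPER = "hypermethylated"
HYPO = "hypomethylated"
NOT_SELECTED = "not_selected"


@dataclass
class BetaMatrix:
    """Probes x samples beta-value matrix with annotations.

    Attributes
    ----------
    probes : DataFrame with columns probe_id, chrom, pos, cross_reactive, snp
    samples : DataFrame with columns sample_id, group (``islet``/``control``)
    beta : (n_probes, n_samples) float array in [0, 1]
    detection_p : (n_probes, n_samples) float array in [0, 1]
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    beta: np.ndarray
    detection_p: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.detection_p = np.asarray(self.detection_p, dtype=float)
        np_, ns = self.beta.shape
        if len(self.probes) != np_ or len(self.samples) != ns:
            raise ValueError("annotation / matrix shape mismatch")
        if self.detection_p.shape != self.beta.shape:
            raise ValueError("detection_p shape mismatch")
        for arr, what in ((self.beta, "beta"), (self.detection_p, "detection p")):
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise ValueError(f"{what} values outside [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.samples["group"] == group).to_numpy()

    def subset_probes(self, keep: np.ndarray) -> "BetaMatrix":
        return BetaMatrix(
            probes=self.probes.loc[keep].reset_index(drop=True),
            samples=self.samples.copy(),
            beta=self.beta[keep],
            detection_p=self.detection_p[keep],
        )


def compute_beta(M, U):
    """Beta value ``M / (U + M)`` from raw methylated/unmethylated intensities.

    Accepts scalars or arrays; raises on negative intensities or M + U == 0.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("intensities must be non-negative")
    total = M + U
    if np.any(total == 0):
        raise ValueError("undefined probe: M + U == 0")
    out = M / total
    return float(out) if out.ndim == 0 else out


def qc_filter(
    bm: BetaMatrix, detection_threshold: float = 0.05, rule: str = "any"
) -> BetaMatrix:
    """Remove artifact probes and probes failing the detection-p threshold.

    Probes flagged cross-reactive (multi-locus hybridisation) or
    SNP-containing are dropped unconditionally.  A probe fails detection QC
    when its detection p exceeds ``detection_threshold`` in any sample
    (``rule="any"``, default) or in more than half of samples
    (``rule="majority"``).  Samples are never removed.
    """
    if not 0.0 < detection_threshold < 1.0:
        raise ValueError("detection_threshold must be in (0, 1)")
    if rule not in ("any", "majority"):
        raise ValueError("rule must be 'any' or 'majority'")

    cross = bm.probes["cross_reactive"].to_numpy(bool)
    snp = bm.probes["snp"].to_numpy(bool)
    fails = bm.detection_p > detection_threshold
    if rule == "any":
        detect_bad = fails.any(axis=1)
    else:
        detect_bad = fails.mean(axis=1) > 0.5

    keep = ~(cross | snp | detect_bad)
    logger.info(
        "qc_filter: %d cross-reactive, %d SNP, %d detection-p failures; %d/%d retained",
        int(cross.sum()), int(snp.sum()), int((detect_bad & ~cross & ~snp).sum()),
        int(keep.sum()), bm.n_probes,
    )
    if not keep.any():
        raise ValueError("no probes left after QC filtering")
    return bm.subset_probes(keep)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Exact null distribution when the combined sample size is at most
    ``EXACT_MW_MAX_N`` and the data are tie-free; otherwise the normal
    approximation with tie and continuity correction.  All-constant input
    returns p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_methylation(
    bm: BetaMatrix, abs_delta_min: float = 0.5, q_max: float = 0.001
) -> pd.DataFrame:
    """Per-probe islet-vs-control comparison.

    Returns one row per probe with group means, delta beta (islet − control),
    the Mann-Whitney U statistic and two-sided p, BH q across all tested
    probes, and a status assigned by :func:`select_markers` at the given
    thresholds.
    """
    islet = bm.group_mask(ISLET)
    ctrl = bm.group_mask(CONTROL)
    if islet.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("need >= 2 samples per group")

    bi = bm.beta[:, islet]
    bc = bm.beta[:, ctrl]
    mean_i = bi.mean(axis=1)
    mean_c = bc.mean(axis=1)

    us = np.empty(bm.n_probes)
    ps = np.empty(bm.n_probes)
    for k in range(bm.n_probes):
        us[k], ps[k] = mann_whitney_u(bi[k], bc[k])
    qs = bh_adjust(ps)

    records = pd.DataFrame(
        {
            "probe_id": bm.probes["probe_id"].to_numpy(),
            "chrom": bm.probes["chrom"].to_numpy(),
            "pos": bm.probes["pos"].to_numpy(),
            "mean_islet": mean_i,
            "mean_control": mean_c,
            "delta_beta": mean_i - mean_c,
            "mw_u": us,
            "p_value": ps,
            "q_value": qs,
        }
    )
    select_markers(records, abs_delta_min=abs_delta_min, q_max=q_max)
    return records


@dataclass
class MarkerSelection:
    """Hyper/hypo marker lists produced by :func:`select_markers`."""

    selected: pd.DataFrame
    hyper: pd.DataFrame
    hypo: pd.DataFrame

    @property
    def n_hyper(self) -> int:
        return len(self.hyper)

    @property
    def n_hypo(self) -> int:
        return len(self.hypo)


def select_markers(
    records: pd.DataFrame, abs_delta_min: float = 0.5, q_max: float = 0.001
) -> MarkerSelection:
    """Apply the |delta beta| / q selection rule and call direction.

    Keeps records with ``|delta_beta| > abs_delta_min`` and ``q < q_max``;
    among those, positive delta beta (islet higher) is hypermethylated and
    negative is hypomethylated.  The ``status`` column of ``records`` is
    (re)written in place; empty output is allowed.
    """
    for thr, name in ((abs_delta_min, "abs_delta_min"), (q_max, "q_max")):
        if not 0.0 < thr < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    keep = (records["delta_beta"].abs() > abs_delta_min) & (records["q_value"] < q_max)
    status = np.where(
        ~keep, NOT_SELECTED, np.where(records["delta_beta"] > 0, HYPER, HYPO)
    )
    records["status"] = status
    selected = records.loc[keep].copy()
    return MarkerSelection(
        selected=selected,
        hyper=selected.loc[selected["status"] == HYPER].copy(),
        hypo=selected.loc[selected["status"] == HYPO].copy(),
    )


def rank_top(records: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k selected markers by |delta beta| desc, then q asc, then probe id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sel = records.loc[records["status"] != NOT_SELECTED].copy()
    sel["_abs_db"] = sel["delta_beta"].abs()
    sel = sel.sort_values(
        ["_abs_db", "q_value", "probe_id"], ascending=[False, True, True]
    ).drop(columns="_abs_db").reset_index(drop=True)
    if k > len(sel):
        warnings.warn(
            f"requested top {k} but only {len(sel)} markers selected", stacklevel=2
        )
        return sel
    return sel.head(k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# file I/O (formats written by synthetic_data.write_beta_matrix)

def read_beta_matrix(beta_tsv, annot_tsv, samples_csv, detection_tsv=None) -> BetaMatrix:
    """Assemble a :class:`BetaMatrix` from its on-disk representation.

    ``beta_tsv``/``detection_tsv``: probes x samples tables indexed by
    probe_id with sample-id columns; ``annot_tsv``: probe_id, chrom, pos,
    cross_reactive, snp; ``samples_csv``: sample_id, group.  A missing
    detection table is treated as all-zero (every probe detected).
    """
    beta = pd.read_csv(beta_tsv, sep="\t", index_col=0)
    annot = pd.read_csv(annot_tsv, sep="\t")
    samples = pd.read_csv(samples_csv)
    annot = annot.set_index("probe_id").loc[beta.index].reset_index()
    beta = beta[samples["sample_id"].tolist()]
    if detection_tsv is not None:
        det = pd.read_csv(detection_tsv, sep="\t", index_col=0)
        det = det.loc[beta.index, samples["sample_id"].tolist()].to_numpy(float)
    else:
        det = np.zeros(beta.shape)
    return BetaMatrix(
        probes=annot, samples=samples, beta=beta.to_numpy(float), detection_p=det
    )
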