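"""Cohort-level serum cfDNA statistics.

Serum levels of the four differentially methylated species (unmethylated and
methylated INS and CHTOP-817, copies/µL) are heavily right-skewed, so group
comparisons are nonparametric: a Kruskal-Wallis omnibus test across cohorts
followed by rank-based many-to-one comparisons of each cohort against the
healthy-control group (Dunn's z on pooled midranks with Šidák adjustment
over the g-1 comparisons; a parametric Dunnett test on log levels is
available behind a flag).  Cohort characteristics (age, BMI Z-score, HbA1c)
are compared with classical one-way ANOVA.

Levels are displayed on a log10(copies/µL + 1) scale; rank tests are
invariant under this monotone transform, so testing on raw or log levels is
equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SPECIES",
    "GroupComparisonResult",
    "log_transform",
    "kruskal_wallis",
    "posthoc_vs_control",
    "analyze_cohorts",
    "anova_oneway",
    "cohort_stripplot",
]

SPECIES = ("u_CHTOP817", "m_CHTOP817", "u_INS", "m_INS")

DEFAULT_ALPHA = 0.05


def log_transform(copies):
    """log10(copies/µL + 1); the +1 offset keeps zero measurable and monotone."""
    x = np.asarray(copies, dtype=float)
    if np.any(x < 0):
        raise ValueError("copies/µL must be non-negative")
    out = np.log10(x + 1.0)
    return float(out) if out.ndim == 0 else out


def _check_groups(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
        if not np.all(np.isfinite(g)):
            raise ValueError("values must be finite")
    return groups


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with g-1 df.

    All observations identical gives (H, p) = (0, 1) by convention.
    """
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparisonResult:
    """Omnibus + many-to-one comparison results for one DNA species."""

    species: str
    omnibus_stat: float
    omnibus_p: float
    table: pd.DataFrame  # cohort, n, z/stat, p, p_adj, direction, significant
    alpha: float = DEFAULT_ALPHA
    method: str = "dunn"


def _dunn_vs_control(
    groups: dict[str, np.ndarray], control_label: str, alpha: float
) -> pd.DataFrame:
    """Dunn's rank-based many-to-one z tests with Šidák adjustment."""
    labels = list(groups)
    pooled = np.concatenate([groups[l] for l in labels])
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie term of the Dunn variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term

    mean_rank = {}
    start = 0
    for l in labels:
        n_l = len(groups[l])
        mean_rank[l] = float(ranks[start : start + n_l].mean())
        start += n_l

    others = [l for l in labels if l != control_label]
    m = len(others)
    rows = []
    for l in others:
        n_i, n_c = len(groups[l]), len(groups[control_label])
        se = np.sqrt(base_var * (1.0 / n_i + 1.0 / n_c))
        diff = mean_rank[l] - mean_rank[control_label]
        z = diff / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = 1.0 - (1.0 - min(p, 1.0)) ** m  # Šidák over the g-1 comparisons
        rows.append(
            {
                "cohort": l,
                "n": n_i,
                "stat": z,
                "p": p,
                "p_adj": p_adj,
                "direction": "higher" if diff > 0 else ("lower" if diff < 0 else "none"),
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def _dunnett_vs_control(
    groups: dict[str, np.ndarray], control_label: str, alpha: float
) -> pd.DataFrame:
    """Parametric Dunnett many-to-one test on log10(x+1) levels."""
    others = [l for l in groups if l != control_label]
    logged = {l: log_transform(groups[l]) for l in groups}
    res = stats.dunnett(*[logged[l] for l in others], control=logged[control_label])
    rows = []
    for i, l in enumerate(others):
        diff = logged[l].mean() - logged[control_label].mean()
        rows.append(
            {
                "cohort": l,
                "n": len(groups[l]),
                "stat": float(res.statistic[i]),
                "p": float(res.pvalue[i]),
                "p_adj": float(res.pvalue[i]),  # Dunnett p is already familywise
                "direction": "higher" if diff > 0 else ("lower" if diff < 0 else "none"),
                "significant": bool(res.pvalue[i] < alpha),
            }
        )
    return pd.DataFrame(rows)


def posthoc_vs_control(
    df: pd.DataFrame,
    species: str,
    control_label: str,
    alpha: float = DEFAULT_ALPHA,
    method: str = "dunn",
    cohort_col: str = "cohort",
) -> GroupComparisonResult:
    """Omnibus Kruskal-Wallis plus each-cohort-vs-control comparisons.

    ``method="dunn"`` (default) runs Dunn's rank-based z on pooled midranks
    with Šidák multiplicity adjustment; ``method="dunnett"`` runs the
    parametric Dunnett test on log10(x+1) levels.
    """
    if control_label not in set(df[cohort_col]):
        raise ValueError(f"control cohort {control_label!r} missing")
    groups = {
        str(l): g[species].to_numpy(float) for l, g in df.groupby(cohort_col, sort=False)
    }
    if len(groups) < 2:
        raise ValueError("need at least one non-control cohort")
    _check_groups(groups.values())
    h, p = kruskal_wallis(*groups.values())
    if method == "dunn":
        table = _dunn_vs_control(groups, control_label, alpha)
    elif method == "dunnett":
        table = _dunnett_vs_control(groups, control_label, alpha)
    else:
        raise ValueError("method must be 'dunn' or 'dunnett'")
    return GroupComparisonResult(
        species=species, omnibus_stat=h, omnibus_p=p, table=table,
        alpha=alpha, method=method,
    )


def analyze_cohorts(
    df: pd.DataFrame,
    control_label: str,
    alpha: float = DEFAULT_ALPHA,
    species=SPECIES,
    method: str = "dunn",
) -> dict[str, GroupComparisonResult]:
    """Run the omnibus + post hoc analysis for every DNA species."""
    return {
        sp: posthoc_vs_control(df, sp, control_label, alpha=alpha, method=method)
        for sp in species
    }


def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p.

    All observations identical gives (F, p) = (0, 1) by convention;
    zero within-group variance with unequal means gives (inf, 0).
    """
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    within_ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if within_ss == 0.0:
        return float("inf"), 0.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def cohort_stripplot(df: pd.DataFrame, species: str, path, control_label=None,
                     cohort_col: str = "cohort"):
    """Strip plot of log10(x+1) levels per cohort (figure-style display)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cohorts = list(dict.fromkeys(df[cohort_col]))
    fig, ax = plt.subplots(figsize=(1.2 * len(cohorts) + 1, 3.5))
    rng = np.random.default_rng(0)
    for i, c in enumerate(cohorts):
        y = log_transform(df.loc[df[cohort_col] == c, species].to_numpy(float))
        x = i + rng.uniform(-0.15, 0.15, size=len(y))
        ax.plot(x, y, "o", ms=4, alpha=0.7)
        ax.hlines(y.mean(), i - 0.25, i + 0.25, color="k")
    ax.set_xticks(range(len(cohorts)), cohorts, rotation=30, ha="right")
    ax.set_ylabel(f"log10({species} + 1), copies/µL")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
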