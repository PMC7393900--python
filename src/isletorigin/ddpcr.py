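"""Droplet digital PCR: gating, Poisson quantification, linearity.

A sample is partitioned into ~20,000 nanolitre-scale droplets and
end-point-amplified with two fluorescent probes (FAM reporting the
unmethylated allele, VIC the methylated allele).  Template molecules
distribute over droplets as Poisson, so the mean occupancy per droplet
follows from the fraction of negative droplets alone:

    lambda = -ln(n_negative / n_total),   concentration = lambda / volume

in copies/µL with ``volume`` the per-droplet volume in µL.  Because the
estimator only needs the negative fraction, each channel is quantified
independently — a droplet is negative on channel i iff its channel-i
amplitude is below that channel's threshold, regardless of the other
channel ("standard multiplex treatment"); intermediate-amplitude "rain"
is handled purely by the threshold, no droplets are excluded.

The per-sample unmethylated fraction u/(u+m) of a marker is the feature
consumed by the tissue-of-origin classifier and the heatmap tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DropletWell",
    "GateCounts",
    "QuantResult",
    "LinearityReport",
    "SaturationError",
    "SeparationError",
    "auto_threshold",
    "gate",
    "quantify",
    "quantify_well",
    "methylation_fraction",
    "linearity",
    "read_droplet_csv",
]

#: default per-droplet volume, µL (0.85 nL; platform-class standard)
DEFAULT_DROPLET_VOLUME = 8.5e-4

#: "auto" threshold = negative-cluster mean + AUTO_K * sd
AUTO_K = 5.0


class SaturationError(ValueError):
    """All droplets positive: lambda unbounded, concentration undefined."""


class SeparationError(ValueError):
    """Automatic thresholding failed: amplitude clusters not separable."""


@dataclass
class DropletWell:
    """Per-droplet two-channel amplitudes for one well."""

    well_id: str
    ch1: np.ndarray  # FAM amplitudes
    ch2: np.ndarray  # VIC amplitudes
    volume: float = DEFAULT_DROPLET_VOLUME

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValueError("channel amplitude arrays must be 1-D and equal length")
        if self.n_droplets < 1:
            raise ValueError("well must contain at least one droplet")
        if self.volume <= 0:
            raise ValueError("droplet volume must be positive")

    @property
    def n_droplets(self) -> int:
        return self.ch1.size


@dataclass(frozen=True)
class GateCounts:
    """Quadrant counts from 2-D gating of one well."""

    double_negative: int
    ch1_only: int
    ch2_only: int
    double_positive: int

    @property
    def n_total(self) -> int:
        return self.double_negative + self.ch1_only + self.ch2_only + self.double_positive

    @property
    def n_negative_ch1(self) -> int:
        # negative on ch1 regardless of ch2
        return self.double_negative + self.ch2_only

    @property
    def n_negative_ch2(self) -> int:
        return self.double_negative + self.ch1_only


@dataclass(frozen=True)
class QuantResult:
    """Poisson quantification of one target/channel in one well."""

    n_total: int
    n_negative: int
    lam: float              # mean copies per droplet
    concentration: float    # copies/µL
    ci_low: float
    ci_high: float
    saturated: bool = False


def auto_threshold(amplitudes: np.ndarray, k: float = AUTO_K) -> float:
    """Set a channel threshold at negative-cluster mean + k*sd.

    Two-pass scheme: a provisional mid-range cut separates the clusters,
    the negative (lower) cluster statistics are then estimated below it.
    Raises :class:`SeparationError` when the resulting clusters are not
    bimodally separated (cluster means closer than twice the summed sds),
    which also catches single-cluster wells.
    """
    a = np.asarray(amplitudes, dtype=float)
    mid = a.min() + 0.5 * (a.max() - a.min())
    neg = a[a <= mid]
    pos = a[a > mid]
    if neg.size == 0 or pos.size == 0:
        raise SeparationError("no bimodal structure in amplitudes")
    mu_n, sd_n = neg.mean(), neg.std()
    mu_p, sd_p = pos.mean(), pos.std()
    if mu_p - mu_n < 2.0 * (sd_n + sd_p):
        raise SeparationError(
            f"clusters not separable (means {mu_n:.0f}/{mu_p:.0f}, sds {sd_n:.0f}/{sd_p:.0f})"
        )
    return mu_n + k * sd_n


def gate(well: DropletWell, thresholds="auto", k: float = AUTO_K) -> GateCounts:
    """Assign every droplet to a quadrant by per-channel thresholds.

    ``thresholds`` is a (ch1, ch2) pair of positive amplitude cutoffs, or
    ``"auto"`` to place each at negative-cluster mean + k*sd (estimated from
    the lower amplitude mode; see :func:`auto_threshold`).
    """
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValueError("thresholds must be a pair of cutoffs or 'auto'")
        t1 = auto_threshold(well.ch1, k=k)
        t2 = auto_threshold(well.ch2, k=k)
    else:
        t1, t2 = float(thresholds[0]), float(thresholds[1])
        if t1 <= 0 or t2 <= 0:
            raise ValueError("thresholds must be positive")
    p1 = well.ch1 > t1
    p2 = well.ch2 > t2
    return GateCounts(
        double_negative=int((~p1 & ~p2).sum()),
        ch1_only=int((p1 & ~p2).sum()),
        ch2_only=int((~p1 & p2).sum()),
        double_positive=int((p1 & p2).sum()),
    )


def _quantify_channel(
    n_negative: int, n_total: int, volume: float, conf: float = 0.95
) -> QuantResult:
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if volume <= 0:
        raise ValueError("volume must be positive")
    if n_negative > n_total:
        raise ValueError("n_negative exceeds n_total")
    if n_negative == 0:
        raise SaturationError(
            "all droplets positive: concentration above the quantifiable range"
        )
    p_neg = n_negative / n_total
    lam = -math.log(p_neg)
    # binomial (Clopper-Pearson) CI on the negative fraction, propagated
    # through the monotone-decreasing map p -> -ln(p)/v
    ci = stats.binomtest(n_negative, n_total).proportion_ci(
        confidence_level=conf, method="exact"
    )
    lo = -math.log(ci.high) / volume if ci.high > 0 else math.inf
    hi = -math.log(ci.low) / volume if ci.low > 0 else math.inf
    return QuantResult(
        n_total=n_total,
        n_negative=n_negative,
        lam=lam,
        concentration=lam / volume,
        ci_low=max(lo, 0.0),
        ci_high=hi,
        saturated=False,
    )


def quantify(counts: GateCounts, volume: float) -> dict[str, QuantResult]:
    """Poisson quantification of both channels from quadrant counts.

    For channel i the negative count is the number of droplets below the
    channel-i threshold regardless of the other channel.  Raises
    :class:`SaturationError` when a channel has no negative droplets.
    """
    return {
        "ch1": _quantify_channel(counts.n_negative_ch1, counts.n_total, volume),
        "ch2": _quantify_channel(counts.n_negative_ch2, counts.n_total, volume),
    }


def quantify_well(well: DropletWell, thresholds="auto", k: float = AUTO_K) -> dict[str, QuantResult]:
    """Gate then quantify a well in one call."""
    return quantify(gate(well, thresholds=thresholds, k=k), well.volume)


def methylation_fraction(u, m) -> float:
    """Unmethylated fraction u/(u+m) from the two concentrations of a marker.

    Accepts :class:`QuantResult` objects or plain copies/µL floats from the
    same well/sample.  Both zero → NaN with a warning (undefined fraction).
    """
    uc = u.concentration if isinstance(u, QuantResult) else float(u)
    mc = m.concentration if isinstance(m, QuantResult) else float(m)
    if uc < 0 or mc < 0:
        raise ValueError("concentrations must be non-negative")
    if uc + mc == 0:
        warnings.warn("both concentrations zero: fraction undefined", stacklevel=2)
        return float("nan")
    return uc / (uc + mc)


@dataclass(frozen=True)
class LinearityReport:
    """Log-log dilution linearity fit and the lowest linear concentration."""

    slope: float
    intercept: float
    r_squared: float
    lowest_linear_conc: float  # copies/µL; NaN if nothing passes
    table: pd.DataFrame        # true_conc, mean_recovered, rel_error, linear


def linearity(series, rel_error_max: float = 0.25) -> LinearityReport:
    """Assess dilution-series linearity of recovered concentrations.

    ``series`` is a list of ``(true_conc, [QuantResult, ...])`` pairs (>= 3
    concentrations, >= 1 replicate each).  A least-squares line is fitted to
    log10(mean recovered) vs log10(true) over concentrations with nonzero
    mean recovery; the lowest linear concentration is the smallest true
    concentration whose mean relative recovery error is below
    ``rel_error_max``.
    """
    rows = []
    for true_conc, reps in series:
        if true_conc <= 0:
            raise ValueError("true concentrations must be positive")
        if len(reps) < 1:
            raise ValueError("need at least one replicate per concentration")
        concs = [r.concentration if isinstance(r, QuantResult) else float(r) for r in reps]
        mean_rec = float(np.mean(concs))
        rows.append(
            {
                "true_conc": float(true_conc),
                "mean_recovered": mean_rec,
                "rel_error": abs(mean_rec - true_conc) / true_conc,
                "n_replicates": len(concs),
            }
        )
    table = pd.DataFrame(rows).sort_values("true_conc").reset_index(drop=True)
    table["linear"] = table["rel_error"] < rel_error_max

    usable = table.loc[table["mean_recovered"] > 0]
    if len(usable) < 3:
        raise ValueError("need >= 3 concentrations with nonzero recovery")
    fit = stats.linregress(
        np.log10(usable["true_conc"]), np.log10(usable["mean_recovered"])
    )
    passing = table.loc[table["linear"], "true_conc"]
    lowest = float(passing.min()) if len(passing) else float("nan")
    return LinearityReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        lowest_linear_conc=lowest,
        table=table,
    )


def read_droplet_csv(path, volume: float = DEFAULT_DROPLET_VOLUME) -> dict[str, DropletWell]:
    """Read a droplet amplitude CSV (well, droplet_index, ch1_amplitude, ch2_amplitude)."""
    df = pd.read_csv(path)
    wells = {}
    for well_id, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("droplet_index")
        wells[str(well_id)] = DropletWell(
            well_id=str(well_id),
            ch1=grp["ch1_amplitude"].to_numpy(float),
            ch2=grp["ch2_amplitude"].to_numpy(float),
            volume=volume,
        )
    return wells
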