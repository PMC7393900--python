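"""Synthetic inputs for every stage of the islet cfDNA methylation pipeline.

Real inputs to the pipeline are methylation-array beta matrices, amplicon
bisulfite reads, droplet-dPCR amplitude tables, and per-subject serum
quantification tables.  The generators here emulate each of them with the
statistical structure the downstream methods assume, so every stage can be
exercised and validated without external data:

* :func:`gen_beta_matrix` — islet vs control beta matrices with a known set
  of truly differential CpGs (half islet-hypermethylated, half
  hypomethylated) at a chosen effect size, plus detection-p failures and
  cross-reactive/SNP artifact probes for the QC stage.
* :func:`gen_tissue_panel` — per-tissue unmethylated-fraction panels for the
  four markers (INS, CHTOP-817/-800/-824) following the complementary
  pattern seen across human tissues: every non-pancreatic tissue is > 50%
  methylated at INS (adipose and skin only ~55-60%), while skeletal muscle,
  brain and heart are <= 50% methylated at CHTOP; beta and alpha cells are
  hypomethylated at both genes.
* :func:`gen_droplet_well` — two-channel droplet amplitude tables at known
  copies/µL: per-droplet occupancy is Poisson(conc x droplet volume),
  occupied droplets draw positive-cluster amplitudes, empty droplets
  negative-cluster amplitudes, channels independent.
* :func:`gen_serum_cohorts` — per-subject serum copies/µL of the four
  species (unmethylated/methylated x INS/CHTOP-817), log-normal around a
  healthy baseline with cohort-specific fold shifts (T1D and FDR elevated in
  all four species; sepsis in the methylated species only; obese in uINS,
  uCHTOP and mINS but not mCHTOP).
* :func:`gen_bisulfite_reads` — bisulfite-converted amplicon reads with
  per-CpG Bernoulli methylation and an optional conversion-failure rate.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bisulfite
from .array_dm import BetaMatrix
from .ddpcr import DEFAULT_DROPLET_VOLUME, DropletWell

__all__ = [
    "MARKERS",
    "SPECIES",
    "TissueProfile",
    "TissueProfileConfig",
    "CohortEffect",
    "CohortEffectSpec",
    "AmplitudeParams",
    "default_tissue_config",
    "default_t1d_cohort_spec",
    "default_obesity_cohort_spec",
    "default_sepsis_cohort_spec",
    "gen_beta_matrix",
    "gen_tissue_panel",
    "gen_droplet_well",
    "gen_serum_cohorts",
    "gen_bisulfite_reads",
    "write_beta_matrix",
    "write_droplet_csv",
]

MARKERS = ("u_INS", "u_CHTOP817", "u_CHTOP800", "u_CHTOP824")
SPECIES = ("u_INS", "m_INS", "u_CHTOP817", "m_CHTOP817")

#: concentration at or above which Beta noise degenerates to the exact mean
CONCENTRATION_CAP = 1e9

#: default Beta-noise concentration for tissue fractions (mean-level dispersion
#: comparable to heatmap variability between donors)
DEFAULT_CONCENTRATION = 50.0


def _beta_draw(rng: np.random.Generator, mean, concentration: float, size=None):
    """Beta draw parameterised by mean and concentration; capped -> exact mean."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-6, 1 - 1e-6)
    if concentration >= CONCENTRATION_CAP:
        return np.broadcast_to(mean, size if size is not None else mean.shape).copy()
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=size)


# ---------------------------------------------------------------------------
# tissue panel

@dataclass(frozen=True)
class TissueProfile:
    """Mean unmethylated fraction per marker plus class labels for one tissue.

    ``concentration`` sets the Beta-noise dispersion (higher = tighter); a
    scalar applies to every marker, a dict sets it per marker (tissues can be
    homogeneous at one locus and variable at another).
    """

    means: dict[str, float]          # marker -> mean unmethylated fraction
    concentration: float | dict[str, float] = DEFAULT_CONCENTRATION
    is_beta: bool = False
    is_alpha: bool = False
    is_islet: bool = False
    is_pancreas: bool = False

    def __post_init__(self) -> None:
        for marker, m in self.means.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"{marker}: mean fraction {m} outside [0, 1]")
        concs = (
            self.concentration.values()
            if isinstance(self.concentration, dict)
            else (self.concentration,)
        )
        if any(c <= 0 for c in concs):
            raise ValueError("concentration must be positive")
        if self.is_beta and not self.is_islet:
            raise ValueError("is_beta implies is_islet")
        if self.is_islet and not self.is_pancreas:
            raise ValueError("is_islet implies is_pancreas")

    def marker_concentration(self, marker: str) -> float:
        if isinstance(self.concentration, dict):
            return float(self.concentration.get(marker, DEFAULT_CONCENTRATION))
        return float(self.concentration)


TissueProfileConfig = dict[str, TissueProfile]


def _profile(ins, c817, c800, c824, concentration=DEFAULT_CONCENTRATION,
             **labels) -> TissueProfile:
    return TissueProfile(
        means={"u_INS": ins, "u_CHTOP817": c817, "u_CHTOP800": c800, "u_CHTOP824": c824},
        concentration=concentration,
        **labels,
    )


def default_tissue_config() -> TissueProfileConfig:
    """Default per-tissue mean unmethylated fractions.

    Encodes the complementary cross-tissue pattern: INS hypomethylated only
    in beta and alpha cells, with adipose and skin the least methylated
    non-pancreatic tissues (~55-60% methylation, and noticeably variable at
    INS between donors); CHTOP hypomethylated in beta cells (within the
    48-99% range) and, to a lesser extent, in alpha cells and whole
    pancreas, while skeletal muscle, brain and heart are at most 50%
    methylated at CHTOP (heart markedly so).  Flow-sorted beta- and
    alpha-cell preparations appear twice, untreated and cytokine-treated,
    with identical profiles (the pattern is unaltered by cytokine
    exposure); sorted alpha preparations are modelled as tighter than bulk
    tissues.  Exact values are configuration, not measurements.
    """
    islet_labels = dict(is_islet=True, is_pancreas=True)
    wide_ins = {"u_INS": 12.0, "u_CHTOP817": 100.0, "u_CHTOP800": 100.0,
                "u_CHTOP824": 100.0}
    beta = _profile(0.82, 0.85, 0.83, 0.86, is_beta=True, **islet_labels)
    alpha = _profile(0.72, 0.62, 0.60, 0.61, concentration=250.0,
                     is_alpha=True, **islet_labels)
    return {
        "beta_cells": beta,
        "beta_cells_cytokine": beta,
        "alpha_cells": alpha,
        "alpha_cells_cytokine": alpha,
        "pancreas": _profile(0.18, 0.55, 0.52, 0.53, is_pancreas=True),
        "adipose": _profile(0.45, 0.04, 0.04, 0.05, concentration=wide_ins),
        "skin": _profile(0.44, 0.05, 0.05, 0.06, concentration=wide_ins),
        "skeletal_muscle": _profile(0.08, 0.56, 0.53, 0.55),
        "brain": _profile(0.06, 0.52, 0.56, 0.53),
        "heart": _profile(0.10, 0.80, 0.76, 0.78),
        "lung": _profile(0.10, 0.15, 0.14, 0.15),
        "thyroid": _profile(0.12, 0.18, 0.16, 0.17),
        "spleen": _profile(0.09, 0.12, 0.12, 0.13),
        "intestine": _profile(0.14, 0.20, 0.18, 0.19),
        "pituitary": _profile(0.11, 0.14, 0.13, 0.14),
        "liver": _profile(0.07, 0.10, 0.10, 0.11),
    }


def gen_tissue_panel(
    config: TissueProfileConfig | None = None,
    n_per_tissue: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-sample tissue panel of unmethylated fractions.

    Each sample's marker fractions are Beta-distributed around the tissue
    mean with the tissue's (per-marker) concentration parameter; class
    labels are copied from the profile.  Returns a DataFrame with columns
    ``sample_id``, ``tissue``, the four marker fractions, and the four
    boolean labels.
    """
    if config is None:
        config = default_tissue_config()
    if not isinstance(n_per_tissue, (int, np.integer)) or n_per_tissue < 1:
        raise ValueError("n_per_tissue must be a positive integer")
    rng = np.random.default_rng(seed)
    rows = []
    for tissue, prof in config.items():
        unknown = set(prof.means) - set(MARKERS)
        if unknown:
            raise ValueError(f"{tissue}: unknown markers {sorted(unknown)}")
        for i in range(n_per_tissue):
            row = {"sample_id": f"{tissue}_{i + 1}", "tissue": tissue}
            for marker in MARKERS:
                row[marker] = float(
                    _beta_draw(rng, prof.means[marker],
                               prof.marker_concentration(marker), size=())
                )
            row.update(
                is_beta=prof.is_beta, is_alpha=prof.is_alpha,
                is_islet=prof.is_islet, is_pancreas=prof.is_pancreas,
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta matrix

def gen_beta_matrix(
    n_islet: int = 64,
    n_control: int = 27,
    n_true_dm: int = 200,
    n_null: int = 2000,
    effect: float = 0.7,
    seed: int = 0,
    concentration: float = DEFAULT_CONCENTRATION,
    detection_fail_frac: float = 0.02,
    cross_reactive_frac: float = 0.01,
    snp_frac: float = 0.01,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Simulate an islet-vs-control beta matrix with known truth.

    ``n_true_dm`` probes differ between groups by ~``effect`` in mean beta
    (half islet-hypermethylated, half hypomethylated); ``n_null`` probes
    share a common per-probe Beta distribution in both groups.  A
    ``detection_fail_frac`` fraction of all probes gets one sample with
    detection p > 0.05; ``cross_reactive_frac``/``snp_frac`` fractions of
    the *null* probes are flagged as array artifacts (truth-labelled probes
    stay clean so truth means "genuinely differential and assayable").

    Returns the matrix and a truth table (probe_id, true_dm, direction).
    """
    for name, v in (("n_islet", n_islet), ("n_control", n_control),
                    ("n_true_dm", n_true_dm), ("n_null", n_null)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if n_islet < 2 or n_control < 2:
        raise ValueError("need at least 2 samples per group")
    if not 0.0 < effect <= 1.0:
        raise ValueError("effect must be in (0, 1]")
    rng = np.random.default_rng(seed)

    n_probes = n_true_dm + n_null
    n_hyper = n_true_dm // 2
    n_hypo = n_true_dm - n_hyper

    lo, hi = 0.02, 0.98
    mean_islet = np.empty(n_probes)
    mean_control = np.empty(n_probes)
    direction = np.array([""] * n_probes, dtype=object)

    # hypermethylated in islets: control low, islet = control + effect
    base = rng.uniform(lo, max(hi - effect, lo + 1e-3), size=n_hyper)
    mean_control[:n_hyper] = base
    mean_islet[:n_hyper] = np.minimum(base + effect, hi)
    direction[:n_hyper] = "hyper"
    # hypomethylated in islets: control high, islet = control - effect
    base = rng.uniform(min(lo + effect, hi - 1e-3), hi, size=n_hypo)
    mean_control[n_hyper:n_true_dm] = base
    mean_islet[n_hyper:n_true_dm] = np.maximum(base - effect, lo)
    direction[n_hyper:n_true_dm] = "hypo"
    # null probes: one common mean per probe
    null_means = rng.uniform(0.05, 0.95, size=n_null)
    mean_control[n_true_dm:] = null_means
    mean_islet[n_true_dm:] = null_means

    beta = np.empty((n_probes, n_islet + n_control))
    beta[:, :n_islet] = _beta_draw(
        rng, mean_islet[:, None], concentration, size=(n_probes, n_islet)
    )
    beta[:, n_islet:] = _beta_draw(
        rng, mean_control[:, None], concentration, size=(n_probes, n_control)
    )

    detection_p = rng.uniform(0.0, 0.04, size=beta.shape)
    n_fail = int(round(detection_fail_frac * n_probes))
    if n_fail:
        fail_probes = rng.choice(n_probes, size=n_fail, replace=False)
        fail_samples = rng.integers(0, beta.shape[1], size=n_fail)
        detection_p[fail_probes, fail_samples] = rng.uniform(0.051, 0.5, size=n_fail)

    cross = np.zeros(n_probes, dtype=bool)
    snp = np.zeros(n_probes, dtype=bool)
    null_idx = np.arange(n_true_dm, n_probes)
    n_cross = int(round(cross_reactive_frac * n_null))
    n_snp = int(round(snp_frac * n_null))
    if n_cross:
        cross[rng.choice(null_idx, size=n_cross, replace=False)] = True
    if n_snp:
        snp[rng.choice(null_idx, size=n_snp, replace=False)] = True

    probe_ids = np.array([f"cg{k:08d}" for k in range(n_probes)])
    probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": rng.choice([f"chr{c}" for c in range(1, 23)], size=n_probes),
            "pos": rng.integers(1, 2_000_000_00, size=n_probes),
            "cross_reactive": cross,
            "snp": snp,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"islet_{i + 1}" for i in range(n_islet)]
            + [f"control_{i + 1}" for i in range(n_control)],
            "group": ["islet"] * n_islet + ["control"] * n_control,
        }
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "true_dm": np.arange(n_probes) < n_true_dm,
            "direction": direction,
        }
    )
    bm = BetaMatrix(probes=probes, samples=samples, beta=beta, detection_p=detection_p)
    return bm, truth


# ---------------------------------------------------------------------------
# droplet wells

@dataclass(frozen=True)
class AmplitudeParams:
    """Gaussian amplitude-cluster parameters for one channel."""

    neg_mean: float = 1000.0
    neg_sd: float = 200.0
    pos_mean: float = 5000.0
    pos_sd: float = 300.0


DEFAULT_AMPLITUDES = (AmplitudeParams(), AmplitudeParams(pos_mean=4500.0))


def gen_droplet_well(
    conc_per_target: tuple[float, float],
    n_droplets: int = 20000,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME,
    amplitude_params: tuple[AmplitudeParams, AmplitudeParams] = DEFAULT_AMPLITUDES,
    seed: int = 0,
    well_id: str = "A01",
) -> DropletWell:
    """Simulate one multiplex droplet well at known copies/µL per channel.

    Per target, droplet occupancy is Poisson(conc x droplet_volume);
    occupied droplets draw positive-cluster amplitudes, empty droplets
    negative-cluster amplitudes, channels independent.  Warns when a
    channel's cluster means are closer than twice the summed sds.
    """
    c1, c2 = conc_per_target
    if c1 < 0 or c2 < 0:
        raise ValueError("concentrations must be non-negative")
    if not isinstance(n_droplets, (int, np.integer)) or n_droplets < 1:
        raise ValueError("n_droplets must be a positive integer")
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be positive")
    rng = np.random.default_rng(seed)

    channels = []
    for conc, par in zip((c1, c2), amplitude_params):
        if par.pos_mean - par.neg_mean < 2.0 * (par.neg_sd + par.pos_sd):
            warnings.warn("amplitude clusters closer than 2 sd: gating may fail",
                          stacklevel=2)
        occ = rng.poisson(conc * droplet_volume, size=n_droplets) > 0
        amps = np.where(
            occ,
            rng.normal(par.pos_mean, par.pos_sd, size=n_droplets),
            rng.normal(par.neg_mean, par.neg_sd, size=n_droplets),
        )
        channels.append(amps)
    return DropletWell(well_id=well_id, ch1=channels[0], ch2=channels[1],
                       volume=droplet_volume)


# ---------------------------------------------------------------------------
# serum cohorts

@dataclass(frozen=True)
class CohortEffect:
    """Per-cohort subject count and fold shifts (vs baseline) per species."""

    n: int
    folds: dict[str, float] = field(default_factory=dict)  # species -> fold, >= 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("subject count must be >= 2")
        for sp, f in self.folds.items():
            if f < 0:
                raise ValueError(f"{sp}: fold must be >= 0")


@dataclass(frozen=True)
class CohortEffectSpec:
    """Baseline log-normal serum levels plus per-cohort fold effects."""

    cohorts: dict[str, CohortEffect]
    baseline_log10_mean: float = 1.0   # log10 copies/µL
    baseline_log10_sd: float = 0.4


#: default fold applied to species reported elevated in a cohort; sized so
#: that the smallest study design (n = 10 controls) reaches rank-test
#: significance reliably (log10 shift ~0.9 over baseline sd 0.4)
ELEVATED_FOLD = 8.0


def default_t1d_cohort_spec() -> CohortEffectSpec:
    """Healthy controls, autoantibody-negative first-degree relatives (FDR),
    and new-onset T1D; the two at-risk/affected cohorts are elevated in all
    four species."""
    up = {sp: ELEVATED_FOLD for sp in SPECIES}
    return CohortEffectSpec(
        cohorts={
            "control": CohortEffect(n=10),
            "FDR": CohortEffect(n=23, folds=dict(up)),
            "T1D": CohortEffect(n=43, folds=dict(up)),
        }
    )


def default_obesity_cohort_spec() -> CohortEffectSpec:
    """Lean controls and four overweight/obese subgroups (by glycemic
    status); obese subgroups are elevated in uINS, uCHTOP-817 and mINS but
    not mCHTOP-817."""
    up = {"u_INS": ELEVATED_FOLD, "u_CHTOP817": ELEVATED_FOLD, "m_INS": ELEVATED_FOLD}
    return CohortEffectSpec(
        cohorts={
            "lean": CohortEffect(n=32),
            "OB-NGT": CohortEffect(n=31, folds=dict(up)),
            "IGT": CohortEffect(n=31, folds=dict(up)),
            "T2D-AAb-": CohortEffect(n=34, folds=dict(up)),
            "T2D-AAb+": CohortEffect(n=22, folds=dict(up)),
        }
    )


def default_sepsis_cohort_spec() -> CohortEffectSpec:
    """Healthy controls vs sepsis; only the methylated species are elevated
    (general cell turnover, not islet-specific)."""
    return CohortEffectSpec(
        cohorts={
            "control": CohortEffect(n=10),
            "sepsis": CohortEffect(n=10, folds={"m_INS": ELEVATED_FOLD,
                                                "m_CHTOP817": ELEVATED_FOLD}),
        }
    )


def gen_serum_cohorts(spec: CohortEffectSpec, seed: int = 0) -> pd.DataFrame:
    """Draw per-subject serum copies/µL of the four species for each cohort.

    Each subject's level of species s is ``fold_s * 10**N(mu, sd)`` with the
    baseline log10 mean/sd from the spec.  Returns columns ``subject_id``,
    ``cohort`` and one column per species.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, eff in spec.cohorts.items():
        unknown = set(eff.folds) - set(SPECIES)
        if unknown:
            raise ValueError(f"{cohort}: unknown species {sorted(unknown)}")
        for i in range(eff.n):
            row = {"subject_id": f"{cohort}_{i + 1}", "cohort": cohort}
            for sp in SPECIES:
                fold = eff.folds.get(sp, 1.0)
                level = fold * 10.0 ** rng.normal(
                    spec.baseline_log10_mean, spec.baseline_log10_sd
                )
                row[sp] = level
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bisulfite reads

def gen_bisulfite_reads(
    ref: bisulfite.AmpliconRef,
    methylation_state,
    n_reads: int,
    conversion_failure: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Simulate bisulfite-converted reads of an amplicon.

    ``methylation_state`` is a scalar or per-CpG array of methylation
    probabilities; each read draws its methylated CpG set independently
    (Bernoulli per site) and is converted with :func:`bisulfite.convert`,
    non-CpG cytosines converting except with probability
    ``conversion_failure``.
    """
    state = np.broadcast_to(
        np.asarray(methylation_state, dtype=float), (len(ref.cpg_positions),)
    )
    if np.any(state < 0) or np.any(state > 1):
        raise ValueError("methylation probabilities must be in [0, 1]")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    positions = np.asarray(ref.cpg_positions)
    reads = []
    for _ in range(n_reads):
        meth = positions[rng.random(len(positions)) < state]
        reads.append(
            bisulfite.convert(ref, meth, conversion_failure=conversion_failure, rng=rng)
        )
    return reads


# ---------------------------------------------------------------------------
# writers

def write_beta_matrix(bm: BetaMatrix, outdir) -> dict[str, Path]:
    """Write a beta matrix to beta.tsv / detection.tsv / annot.tsv / samples.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_ids = bm.samples["sample_id"].tolist()
    probe_ids = bm.probes["probe_id"].tolist()
    paths = {
        "beta": outdir / "beta.tsv",
        "detection": outdir / "detection.tsv",
        "annot": outdir / "annot.tsv",
        "samples": outdir / "samples.csv",
    }
    pd.DataFrame(bm.beta, index=pd.Index(probe_ids, name="probe_id"),
                 columns=sample_ids).to_csv(paths["beta"], sep="\t")
    pd.DataFrame(bm.detection_p, index=pd.Index(probe_ids, name="probe_id"),
                 columns=sample_ids).to_csv(paths["detection"], sep="\t")
    bm.probes.to_csv(paths["annot"], sep="\t", index=False)
    bm.samples.to_csv(paths["samples"], index=False)
    return paths


def write_droplet_csv(wells, path) -> Path:
    """Write wells to a droplet amplitude CSV
    (well, droplet_index, ch1_amplitude, ch2_amplitude)."""
    if isinstance(wells, DropletWell):
        wells = [wells]
    if isinstance(wells, dict):
        wells = list(wells.values())
    frames = [
        pd.DataFrame(
            {
                "well": w.well_id,
                "droplet_index": np.arange(w.n_droplets),
                "ch1_amplitude": w.ch1,
                "ch2_amplitude": w.ch2,
            }
        )
        for w in wells
    ]
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
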