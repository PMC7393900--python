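"""End-to-end orchestration: simulate -> discover -> quantify -> classify -> cohorts.

A single :class:`RunConfig` (constructable from YAML) drives the whole chain.
Reproducibility contract: every stochastic stage derives its random stream
from the top-level seed through a fixed per-stage spawn key, so enabling or
disabling a stage never perturbs another stage's draws, and running the same
config twice produces byte-identical artifacts.  A JSON manifest records all
parameters, per-stage seeds and SHA-256 hashes of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import array_dm, cohort_stats, ddpcr, synthetic_data, tissue_classifier

__all__ = ["RunConfig", "run_all", "stage_seed"]

logger = logging.getLogger(__name__)

# fixed spawn keys: adding a stage never changes existing substreams
_STAGE_IDS = {"simulate": 0, "discover": 1, "quantify": 2, "classify": 3, "cohorts": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the top-level seed (counter-based)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_IDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """All knobs of an end-to-end run."""

    seed: int = 0
    outdir: str = "isletorigin_run"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGE_IDS}
    )
    # simulate
    n_islet: int = 64
    n_control: int = 27
    n_true_dm: int = 200
    n_null: int = 2000
    effect: float = 0.7
    n_per_tissue: int = 6
    well_concentrations: tuple = ((100.0, 100.0), (500.0, 50.0))
    n_droplets: int = 20000
    droplet_volume: float = ddpcr.DEFAULT_DROPLET_VOLUME
    # discover
    detection_threshold: float = 0.05
    abs_delta_min: float = 0.5
    q_max: float = 0.001
    # quantify
    thresholds: object = "auto"
    # classify
    cv_k: int = 5
    cv_reps: int = 100
    # cohorts
    control_label: str = "control"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    seed = stage_seed(cfg.seed, "simulate")
    paths: list[Path] = []

    bm, truth = synthetic_data.gen_beta_matrix(
        cfg.n_islet, cfg.n_control, cfg.n_true_dm, cfg.n_null, cfg.effect, seed=seed
    )
    arraydir = outdir / "array"
    paths.extend(synthetic_data.write_beta_matrix(bm, arraydir).values())
    truth_path = arraydir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    paths.append(truth_path)

    panel = synthetic_data.gen_tissue_panel(n_per_tissue=cfg.n_per_tissue, seed=seed + 1)
    panel_path = outdir / "tissue_panel.csv"
    panel.to_csv(panel_path, index=False)
    paths.append(panel_path)

    wells = [
        synthetic_data.gen_droplet_well(
            tuple(conc), n_droplets=cfg.n_droplets,
            droplet_volume=cfg.droplet_volume, seed=seed + 10 + i,
            well_id=f"W{i + 1:02d}",
        )
        for i, conc in enumerate(cfg.well_concentrations)
    ]
    paths.append(synthetic_data.write_droplet_csv(wells, outdir / "droplets.csv"))

    for name, spec in (
        ("t1d", synthetic_data.default_t1d_cohort_spec()),
        ("obesity", synthetic_data.default_obesity_cohort_spec()),
        ("sepsis", synthetic_data.default_sepsis_cohort_spec()),
    ):
        df = synthetic_data.gen_serum_cohorts(spec, seed=seed + 100 + _hash_name(name))
        p = outdir / f"cohorts_{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def _hash_name(name: str) -> int:
    return int(hashlib.sha1(name.encode()).hexdigest()[:6], 16)


def _stage_discover(cfg: RunConfig, outdir: Path, summary: list[str]) -> list[Path]:
    bm = array_dm.read_beta_matrix(
        outdir / "array" / "beta.tsv",
        outdir / "array" / "annot.tsv",
        outdir / "array" / "samples.csv",
        outdir / "array" / "detection.tsv",
    )
    bm = array_dm.qc_filter(bm, detection_threshold=cfg.detection_threshold)
    records = array_dm.differential_methylation(
        bm, abs_delta_min=cfg.abs_delta_min, q_max=cfg.q_max
    )
    sel = array_dm.select_markers(records, cfg.abs_delta_min, cfg.q_max)
    out = outdir / "markers.csv"
    records.to_csv(out, index=False)
    summary.append(
        f"marker discovery: {len(records)} probes tested, "
        f"{sel.n_hyper} hypermethylated, {sel.n_hypo} hypomethylated"
    )
    return [out]


def _stage_quantify(cfg: RunConfig, outdir: Path, summary: list[str]) -> list[Path]:
    wells = ddpcr.read_droplet_csv(outdir / "droplets.csv", volume=cfg.droplet_volume)
    rows = []
    for well_id, well in wells.items():
        res = ddpcr.quantify_well(well, thresholds=cfg.thresholds)
        for ch, qr in res.items():
            rows.append(
                {
                    "well": well_id,
                    "channel": ch,
                    "n_total": qr.n_total,
                    "n_negative": qr.n_negative,
                    "lambda": qr.lam,
                    "concentration": qr.concentration,
                    "ci_low": qr.ci_low,
                    "ci_high": qr.ci_high,
                }
            )
    out = outdir / "quant.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    summary.append(f"dPCR quantification: {len(wells)} wells, 2 channels each")
    return [out]


def _stage_classify(cfg: RunConfig, outdir: Path, summary: list[str]) -> list[Path]:
    panel = pd.read_csv(outdir / "tissue_panel.csv")
    report = tissue_classifier.repeated_cv(
        panel, k=cfg.cv_k, reps=cfg.cv_reps, seed=stage_seed(cfg.seed, "classify")
    )
    table = tissue_classifier.mean_accuracy_table(report)
    table_path = outdir / "accuracy_table.csv"
    long_path = outdir / "accuracy_per_rep.csv"
    table.to_csv(table_path)
    report.accuracies.to_csv(long_path, index=False)
    summary.append("classification accuracy (%, task x feature set):")
    summary.append(table.round(1).to_string())
    return [table_path, long_path]


def _stage_cohorts(cfg: RunConfig, outdir: Path, summary: list[str]) -> list[Path]:
    paths = []
    controls = {"t1d": cfg.control_label, "obesity": "lean", "sepsis": cfg.control_label}
    for name, control in controls.items():
        src = outdir / f"cohorts_{name}.csv"
        if not src.exists():
            continue
        df = pd.read_csv(src)
        results = cohort_stats.analyze_cohorts(df, control, alpha=cfg.alpha)
        rows = []
        for sp, res in results.items():
            for _, r in res.table.iterrows():
                rows.append(
                    {
                        "species": sp,
                        "omnibus_H": res.omnibus_stat,
                        "omnibus_p": res.omnibus_p,
                        **r.to_dict(),
                    }
                )
        out = outdir / f"cohort_results_{name}.csv"
        pd.DataFrame(rows).to_csv(out, index=False)
        paths.append(out)
        flagged = [
            f"{r['species']}:{r['cohort']}:{r['direction']}"
            for r in rows
            if r["significant"]
        ]
        summary.append(f"cohort study '{name}': flagged {flagged}")
    return paths


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a manifest.

    Returns the manifest dict (also written to ``manifest.json`` along with
    a human-readable ``summary.txt``).  A stage failure aborts the run with
    the failing stage named; artifacts of earlier stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: list[str] = []
    outputs: dict[str, list[str]] = {}

    stage_funcs = {
        "simulate": lambda: _stage_simulate(config, outdir),
        "discover": lambda: _stage_discover(config, outdir, summary),
        "quantify": lambda: _stage_quantify(config, outdir, summary),
        "classify": lambda: _stage_classify(config, outdir, summary),
        "cohorts": lambda: _stage_cohorts(config, outdir, summary),
    }
    for stage in _STAGE_IDS:
        if not config.stages.get(stage, False):
            continue
        logger.info("running stage %s", stage)
        try:
            paths = stage_funcs[stage]()
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        outputs[stage] = [str(p) for p in paths]

    manifest = {
        "config": {
            k: (list(map(list, v)) if k == "well_concentrations" else v)
            for k, v in asdict(config).items()
        },
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_IDS
                        if config.stages.get(s, False)},
        "outputs": {
            stage: {p: _sha256(Path(p)) for p in paths}
            for stage, paths in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return manifest
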