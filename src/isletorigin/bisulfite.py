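"""In-silico bisulfite conversion and per-CpG methylation calling.

Bisulfite treatment deaminates unmethylated cytosine to uracil (sequenced as
T) while 5-methyl-cytosine — in mammalian DNA essentially confined to CpG
dinucleotides — resists conversion and is still read as C.  Comparing the
base observed at a CpG position across reads against the untreated reference
therefore gives a direct per-site methylation fraction.  This module models
that chemistry on the top strand of short amplicons, calls methylation from
aligned read sets, applies a two-point calibration against fully methylated /
fully unmethylated synthetic controls, and validates allele-discriminating
TaqMan probe pairs (the methylated allele retains the CpG cytosine/guanine,
the unmethylated allele carries the converted base).

Coordinates are 1-based throughout: a CpG position is the index of the C of
the CpG dinucleotide.  Only the forward strand is modelled; a reverse-strand
assay is represented by supplying the reverse-complement amplicon explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmpliconRef",
    "ProbeCheck",
    "convert",
    "call_methylation",
    "calibrate",
    "probe_allele_check",
    "read_amplicon_fasta",
    "write_amplicon_fasta",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AmpliconRef:
    """An amplicon reference sequence with annotated CpG positions.

    Parameters
    ----------
    name : str
        Amplicon identifier (e.g. ``"CHTOP-817"``).
    sequence : str
        Uppercase A/C/G/T reference sequence (untreated top strand).
    cpg_positions : tuple of int
        1-based positions of the C of each CpG dinucleotide.
    chrom, start : optional genome anchor
        Chromosome name and 1-based genomic position of the first base.
        Treated as opaque labels.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]
    chrom: str | None = None
    start: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - _VALID_BASES:
            raise ValueError(f"{self.name}: sequence must be non-empty uppercase A/C/G/T")
        for p in self.cpg_positions:
            if not (1 <= p < len(seq)):
                raise ValueError(f"{self.name}: CpG position {p} out of range")
            if seq[p - 1] != "C" or seq[p] != "G":
                raise ValueError(
                    f"{self.name}: position {p} is {seq[p - 1]}{seq[p]}, not CG"
                )

    @classmethod
    def from_sequence(
        cls, name: str, sequence: str, chrom: str | None = None, start: int | None = None
    ) -> "AmpliconRef":
        """Build a reference with CpG positions auto-detected from the sequence."""
        sequence = sequence.upper()
        cpgs = tuple(
            i + 1 for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"
        )
        return cls(name, sequence, cpgs, chrom=chrom, start=start)


def convert(
    ref: AmpliconRef,
    methylated: Iterable[int] = (),
    conversion_failure: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Bisulfite-convert a reference sequence.

    Every cytosine outside the ``methylated`` CpG set becomes T; cytosines of
    methylated CpGs are retained.  With ``conversion_failure > 0`` each
    convertible C independently escapes conversion (stays C) with that
    probability, modelling incomplete treatment.

    Deterministic when ``conversion_failure == 0``.
    """
    meth = set(methylated)
    extra = meth - set(ref.cpg_positions)
    if extra:
        raise ValueError(f"positions {sorted(extra)} are not CpGs in {ref.name}")
    if not 0.0 <= conversion_failure <= 1.0:
        raise ValueError("conversion_failure must be in [0, 1]")
    if conversion_failure > 0.0 and rng is None:
        rng = np.random.default_rng()

    out = list(ref.sequence)
    for i, base in enumerate(out):
        pos = i + 1
        if base != "C" or pos in meth:
            continue
        if conversion_failure > 0.0 and rng.random() < conversion_failure:
            continue  # escaped conversion
        out[i] = "T"
    return "".join(out)


def call_methylation(reads: Sequence[str], ref: AmpliconRef) -> pd.DataFrame:
    """Count methylated (C) vs unmethylated (T) calls per CpG position.

    ``reads`` must be positionally consistent with ``ref`` (simulator output
    or externally aligned, one full-length string per read).  Bases other
    than C/T at a CpG are uninformative and excluded from the total.

    Returns a DataFrame with columns ``position``, ``n_methylated``,
    ``n_total``, ``fraction``; a CpG with zero informative reads gets
    ``fraction = NaN`` and is flagged via the ``undefined`` column.
    """
    if not reads:
        raise ValueError("empty read set")
    positions = list(ref.cpg_positions)
    n_meth = np.zeros(len(positions), dtype=int)
    n_tot = np.zeros(len(positions), dtype=int)
    for read in reads:
        for j, pos in enumerate(positions):
            if pos > len(read):
                continue
            base = read[pos - 1]
            if base == "C":
                n_meth[j] += 1
                n_tot[j] += 1
            elif base == "T":
                n_tot[j] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(n_tot > 0, n_meth / np.maximum(n_tot, 1), np.nan)
    table = pd.DataFrame(
        {
            "position": positions,
            "n_methylated": n_meth,
            "n_total": n_tot,
            "fraction": frac,
            "undefined": n_tot == 0,
        }
    )
    if table["undefined"].any():
        warnings.warn("some CpGs have zero informative reads", stacklevel=2)
    return table


def calibrate(
    raw: pd.DataFrame, meth_control: pd.DataFrame, unmeth_control: pd.DataFrame
) -> pd.DataFrame:
    """Two-point linear calibration against synthetic control templates.

    Per CpG, with m = fraction observed on the fully methylated control and
    u = fraction on the fully unmethylated control, the calibrated fraction is
    ``(raw - u) / (m - u)`` clipped to [0, 1].  CpGs where ``m <= u`` cannot
    be calibrated and are flagged (``calibration_impossible``); values clipped
    at either end are flagged ``clipped``.
    """
    for df in (meth_control, unmeth_control):
        if not np.array_equal(df["position"].to_numpy(), raw["position"].to_numpy()):
            raise ValueError("controls must be measured on the same CpG set")
    m = meth_control["fraction"].to_numpy(float)
    u = unmeth_control["fraction"].to_numpy(float)
    r = raw["fraction"].to_numpy(float)
    impossible = ~(m > u)
    with np.errstate(invalid="ignore", divide="ignore"):
        cal = (r - u) / (m - u)
    clipped = (cal < 0) | (cal > 1)
    cal = np.clip(cal, 0.0, 1.0)
    cal[impossible] = np.nan
    out = raw[["position"]].copy()
    out["raw_fraction"] = r
    out["calibrated_fraction"] = cal
    out["clipped"] = clipped & ~impossible
    out["calibration_impossible"] = impossible
    if impossible.any():
        warnings.warn("calibration impossible at some CpGs (m <= u)", stacklevel=2)
    return out


@dataclass(frozen=True)
class ProbeCheck:
    """Result of comparing an allele-discriminating probe pair."""

    mismatch_positions: tuple[int, ...]  # 1-based
    valid: bool
    bases: tuple[tuple[str, str], ...] = field(default=())


def probe_allele_check(vic_probe: str, fam_probe: str) -> ProbeCheck:
    """Validate a methylated/unmethylated TaqMan probe pair.

    The two probes of a methylation-discriminating assay must be identical
    except at the interrogated base, where bisulfite conversion turns the
    methylated-allele C into T (or, on the opposite strand, G into A).  A
    pair is valid iff there is exactly one mismatch and it is a G/A or C/T
    substitution (in either probe order).
    """
    vic, fam = vic_probe.upper(), fam_probe.upper()
    if len(vic) != len(fam):
        raise ValueError("probes differ in length")
    mism = tuple(i + 1 for i, (a, b) in enumerate(zip(vic, fam)) if a != b)
    bases = tuple((vic[i - 1], fam[i - 1]) for i in mism)
    valid = len(mism) == 1 and frozenset(bases[0]) in ({"G", "A"}, {"C", "T"})
    return ProbeCheck(mismatch_positions=mism, valid=valid, bases=bases)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_amplicon_fasta(path) -> list[AmpliconRef]:
    """Read amplicons from FASTA; CpG positions are auto-detected."""
    return [
        AmpliconRef.from_sequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_amplicon_fasta(refs: Iterable[AmpliconRef], path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.name, description="") for r in refs]
    SeqIO.write(records, str(path), "fasta")
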