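"""On-disk formats, domain types, configuration and logging.

All genomic coordinates are 0-based half-open (BED convention); a TSS is a
single 0-based position. Expression tables are TSV, features in rows and
samples in columns. Position weight matrices use a JASPAR-style text format
(``>motif_id`` header followed by four count rows in A, C, G, T order,
optionally prefixed by the base letter and wrapped in brackets).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("sestrat")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExprMatrix:
    """A features x samples expression table.

    ``scale_tag`` is ``"raw"`` (values >= 0, linear scale) or ``"log2"``
    (log2(x+1)-transformed). The tag exists so the log transform is applied
    exactly once.
    """

    df: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("raw", "log2"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.df.index.duplicated().any():
            dup = self.df.index[self.df.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.df.columns.duplicated().any():
            dup = self.df.columns[self.df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        vals = self.df.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise FormatError("expression matrix contains non-finite values")
        if self.scale_tag == "raw" and vals.size and (vals < 0).any():
            raise FormatError("raw-scale expression matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def to_log2(self) -> "ExprMatrix":
        """Return a log2(x+1)-scale copy; identity if already log2."""
        if self.scale_tag == "log2":
            return self
        return ExprMatrix(np.log2(self.df + 1.0), scale_tag="log2")

    def subset_features(self, ids: Sequence[str]) -> "ExprMatrix":
        missing = [i for i in ids if i not in self.df.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return ExprMatrix(self.df.loc[list(ids)], scale_tag=self.scale_tag)

    def align_samples(self, sample_ids: Sequence[str]) -> "ExprMatrix":
        missing = [s for s in sample_ids if s not in self.df.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExprMatrix(self.df[list(sample_ids)], scale_tag=self.scale_tag)


@dataclass(frozen=True)
class SERegion:
    """A super-enhancer locus, 0-based half-open."""

    se_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"SE {self.se_id!r}: start {self.start} must be < end {self.end}"
            )


@dataclass(frozen=True)
class TssRecord:
    """A gene transcription start site (single 0-based position)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise FormatError(f"gene {self.gene_id!r}: negative TSS")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")


ALPHABET = "ACGT"


@dataclass
class Pwm:
    """A position weight matrix over A,C,G,T (rows of ``probs`` sum to 1)."""

    motif_id: str
    probs: np.ndarray  # L x 4
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise FormatError(f"PWM {self.motif_id!r}: probs must be L x 4 with L >= 1")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise FormatError(f"PWM {self.motif_id!r}: rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, pseudocount: float = 0.01
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise FormatError(f"PWM {motif_id!r}: negative counts")
        if pseudocount <= 0 and (counts.sum(axis=1) == 0).any():
            raise FormatError(f"PWM {motif_id!r}: all-zero column without pseudocount")
        if (counts.sum(axis=1) == 0).any():
            logger.warning("PWM %s has an all-zero column; pseudocount applied", motif_id)
        c = counts + pseudocount
        return cls(motif_id, c / c.sum(axis=1, keepdims=True), pseudocount=pseudocount)


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored time-to-event observation (event: 1=event, 0=censored)."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise FormatError(f"sample {self.sample_id!r}: time must be finite and > 0")
        if self.event not in (0, 1):
            raise FormatError(f"sample {self.sample_id!r}: event must be 0 or 1")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, scale_tag: str = "raw") -> ExprMatrix:
    """Read a TSV expression table (first column feature ids, header sample ids)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if df.isna().any().any():
        r, c = next(zip(*np.nonzero(df.isna().to_numpy())))
        raise FormatError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for c in df.columns:
            col = pd.to_numeric(df[c], errors="coerce")
            if col.isna().any():
                row = df.index[col.isna().to_numpy().nonzero()[0][0]]
                raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {c!r}")
        raise
    return ExprMatrix(df, scale_tag=scale_tag)


def write_expression(matrix: ExprMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="feature_id")


def read_bed(path: str | Path) -> list[SERegion]:
    """Read BED3+1 (chrom, start, end[, name]); 0-based half-open."""
    regions: list[SERegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            if name in seen:
                raise FormatError(f"{path}:{ln}: duplicate SE id {name!r}")
            seen.add(name)
            regions.append(SERegion(name, chrom, start, end))
    return regions


def write_bed(regions: Iterable[SERegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.se_id}\n")


def read_tss(path: str | Path) -> list[TssRecord]:
    """Read a TSS table: TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return [
        TssRecord(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_tss(records: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.tss}\t{r.strand}\n")


_PWM_ROW = re.compile(r"^\s*(?:([ACGT])\s*[\[:|]?)?\s*([0-9. eE+-]+?)\s*\]?\s*$")


def read_pwm_library(path: str | Path, pseudocount: float = 0.01) -> list[Pwm]:
    """Read a JASPAR-style PFM file into probability PWMs.

    Counts are normalized per position after adding ``pseudocount``.
    """
    pwms: list[Pwm] = []
    motif_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, motif_id
        if motif_id is None:
            return
        if len(rows) != 4:
            raise FormatError(f"PWM {motif_id!r}: expected 4 base rows, got {len(rows)}")
        lens = {len(r) for r in rows}
        if len(lens) != 1:
            raise FormatError(f"PWM {motif_id!r}: rows of unequal length")
        counts = np.array(rows, dtype=float).T  # L x 4
        pwms.append(Pwm.from_counts(motif_id, counts, pseudocount=pseudocount))
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
            else:
                m = _PWM_ROW.match(line)
                if m is None:
                    raise FormatError(f"{path}: unparseable PFM row {line!r}")
                rows.append([float(x) for x in m.group(2).split()])
    flush()
    return pwms


def write_pwm_library(pwms: Iterable[Pwm], path: str | Path, scale: float = 100.0) -> None:
    """Write PWMs as JASPAR-style count rows (probabilities scaled)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\n")
            for b, base in enumerate(ALPHABET):
                row = " ".join(f"{v * scale:.4f}" for v in p.probs[:, b])
                fh.write(f"{base} [ {row} ]\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read promoter sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival table: TSV with columns sample_id, time, event."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    recs = []
    for r in df.itertuples(index=False):
        ev = float(r.event)
        if ev not in (0.0, 1.0):
            raise FormatError(f"{path}: sample {r.sample_id!r}: event must be 0 or 1")
        recs.append(SurvivalRecord(r.sample_id, float(r.time), int(ev)))
    return recs


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttime\tevent\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.time!r}\t{r.event}\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    # consensus clustering
    "top_features": 2000,
    "k_min": 2,
    "k_max": 6,
    "n_resamples": 1000,
    "subsample_frac": 0.8,
    "kmeans_n_init": 10,
    "pac_lower": 0.1,
    "pac_upper": 0.9,
    # linkage
    "window_bp": 500_000,
    "corr_method": "spearman",
    "rho_min": 0.3,
    "link_q_max": 0.05,
    "link_sign": "positive",
    # differential expression
    "de_q_max": 0.05,
    "de_lfc_min": 1.0,
    # motif enrichment
    "pwm_threshold_frac": 0.8,
    "pwm_pseudocount": 0.01,
    "motif_q_max": 0.05,
    # TF index
    "cv_folds": 10,
    # survival
    "index_cut": "median",
}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Merge defaults <- YAML config file <- explicit overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: config must be a mapping")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")
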