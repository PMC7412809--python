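"""Readers and writers for the genomic file formats the toolkit touches.

All coordinates are stored 0-based half-open internally.  GTF input
(1-based inclusive) is shifted on read; BED input is taken as-is.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "NamedMatrix",
    "SignatureSet",
    "PWM",
    "read_gene_models",
    "read_peaks",
    "write_peaks",
    "read_matrix",
    "write_matrix",
    "read_signatures",
    "write_signatures",
    "read_pwms",
    "write_pwms",
    "merge_intervals",
]

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals on the same chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


@dataclass
class GeneModel:
    """A gene with a strand-aware TSS, promoter window, and merged exons."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    promoter_flank: int = 2000

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = merge_intervals(self.exons)
        if self.total_exon_length <= 0:
            raise ValueError(f"gene {self.gene_id} has zero exon length")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based position)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def total_exon_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def promoter(self) -> GenomicInterval:
        """Promoter window: TSS +/- promoter_flank."""
        start = max(0, self.tss - self.promoter_flank)
        return GenomicInterval(
            self.interval.chrom, start, self.tss + self.promoter_flank + 1,
            self.interval.strand,
        )


class NamedMatrix:
    """A numeric matrix (dense or sparse) with unique row and column names."""

    def __init__(self, values, row_names, col_names):
        values = values if sp.issparse(values) else np.asarray(values)
        row_names = list(row_names)
        col_names = list(col_names)
        if values.shape != (len(row_names), len(col_names)):
            raise ValueError(
                f"matrix shape {values.shape} does not match names "
                f"({len(row_names)} x {len(col_names)})"
            )
        if len(set(row_names)) != len(row_names):
            raise ValueError("duplicate row names")
        if len(set(col_names)) != len(col_names):
            raise ValueError("duplicate column names")
        self.values = values
        self.row_names = row_names
        self.col_names = col_names

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.row_names, columns=self.col_names)

    def subset_rows(self, names) -> "NamedMatrix":
        idx = {n: i for i, n in enumerate(self.row_names)}
        rows = [idx[n] for n in names]
        vals = self.values.tocsr()[rows] if sp.issparse(self.values) else self.values[rows]
        return NamedMatrix(vals, list(names), self.col_names)

    def subset_cols(self, names) -> "NamedMatrix":
        idx = {n: i for i, n in enumerate(self.col_names)}
        cols = [idx[n] for n in names]
        vals = self.values.tocsc()[:, cols] if sp.issparse(self.values) else self.values[:, cols]
        return NamedMatrix(vals, self.row_names, list(names))


@dataclass
class SignatureSet:
    """Ordered marker-gene lists keyed by cell type."""

    markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell_type, genes in self.markers.items():
            if not genes:
                raise ValueError(f"cell type {cell_type} has no markers")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate marker genes for {cell_type}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    def __getitem__(self, cell_type: str) -> list[str]:
        return self.markers[cell_type]


@dataclass
class PWM:
    """A position weight matrix: L columns of nucleotide probabilities (ACGT)."""

    name: str
    probs: np.ndarray  # shape (L, 4)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must have shape (L, 4)")
        if self.probs.shape[0] < 4:
            raise ValueError("PWM must have at least 4 positions")
        if (self.probs < 0).any():
            raise ValueError("PWM entries must be nonnegative")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        # reverse positions; swap A<->T and C<->G
        return PWM(self.name, self.probs[::-1, ::-1].copy())

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits: 2 + sum p log2 p."""
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.probs > 0, self.probs * np.log2(self.probs), 0.0)
        return 2.0 + plogp.sum(axis=1)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) == 2:
            out[parts[0]] = parts[1].strip().strip('"')
    return out


def read_gene_models(path: str, promoter_flank: int = 2000) -> list[GeneModel]:
    """Read gene models from a GTF or BED12 file.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open;
    BED12 is already 0-based half-open.  Exons are merged per gene; the TSS
    is the strand-aware gene start.
    """
    lower = path.lower()
    if lower.endswith((".gtf", ".gtf.txt")):
        return _read_gene_models_gtf(path, promoter_flank)
    if lower.endswith(".bed") or lower.endswith(".bed12"):
        return _read_gene_models_bed12(path, promoter_flank)
    # sniff: GTF lines have 9 tab fields with attributes containing gene_id "..."
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 9 and "gene_id" in fields[8]:
                return _read_gene_models_gtf(path, promoter_flank)
            return _read_gene_models_bed12(path, promoter_flank)
    raise ValueError(f"empty gene annotation file: {path}")


def _read_gene_models_gtf(path: str, promoter_flank: int) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line (need 9 fields)")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = _parse_gtf_attributes(attrs)
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand if strand in VALID_STRANDS else ".")
            rec = genes.get(gene_id)
            if rec is None:
                rec = {"name": attr.get("gene_name", gene_id), "gene": None, "exons": []}
                genes[gene_id] = rec
                order.append(gene_id)
            if feature == "gene":
                rec["gene"] = iv
                rec["name"] = attr.get("gene_name", rec["name"])
            elif feature == "exon":
                rec["exons"].append(iv)
            elif feature == "transcript" and rec["gene"] is None:
                rec["gene"] = iv
    models = []
    for gene_id in order:
        rec = genes[gene_id]
        if not rec["exons"]:
            raise ValueError(f"gene {gene_id} has no exon records in {path}")
        gene_iv = rec["gene"]
        if gene_iv is None:
            exs = rec["exons"]
            gene_iv = GenomicInterval(
                exs[0].chrom, min(e.start for e in exs), max(e.end for e in exs),
                exs[0].strand,
            )
        models.append(GeneModel(gene_id, rec["name"], gene_iv, rec["exons"], promoter_flank))
    return models


def _read_gene_models_bed12(path: str, promoter_flank: int) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            iv = GenomicInterval(chrom, start, end, strand if strand in VALID_STRANDS else ".")
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, iv.strand)
                for off, size in zip(offsets, sizes)
            ]
            models.append(GeneModel(name, name, iv, exons, promoter_flank))
    return models


def read_peaks(path: str) -> list[GenomicInterval]:
    """Read peak intervals from a BED3+ file (0-based half-open)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED requires at least 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                peaks.append(GenomicInterval(fields[0], start, end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_matrix(path: str) -> NamedMatrix:
    """Read a named matrix.

    ``.mtx`` files use MatrixMarket triplets with sidecar ``.rows`` /
    ``.cols`` name files (one name per line); anything else is parsed as a
    dense TSV with row names in the first column and a header of column
    names.
    """
    if path.endswith(".mtx"):
        base = path[: -len(".mtx")]
        values = scipy.io.mmread(path).tocsr()
        row_names = _read_names(base + ".rows")
        col_names = _read_names(base + ".cols")
        if values.shape[0] != len(row_names) or values.shape[1] != len(col_names):
            raise ValueError(
                f"{path}: matrix is {values.shape} but name files declare "
                f"{len(row_names)} x {len(col_names)}"
            )
        return NamedMatrix(values, row_names, col_names)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return NamedMatrix(df.to_numpy(), [str(x) for x in df.index], [str(x) for x in df.columns])


def _read_names(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing sidecar name file: {path}")
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_matrix(matrix: NamedMatrix, path: str) -> None:
    """Write a NamedMatrix; format chosen by extension (.mtx or .tsv)."""
    if path.endswith(".mtx"):
        base = path[: -len(".mtx")]
        values = matrix.values if sp.issparse(matrix.values) else sp.coo_matrix(matrix.values)
        scipy.io.mmwrite(path, values)
        for names, suffix in ((matrix.row_names, ".rows"), (matrix.col_names, ".cols")):
            with open(base + suffix, "w") as fh:
                fh.write("\n".join(names) + "\n")
    else:
        matrix.to_frame().to_csv(path, sep="\t")


def read_signatures(path: str) -> SignatureSet:
    """Read a two-column TSV (cell_type, gene) into a SignatureSet.

    Per-type order is preserved; exact duplicate rows are dropped; a gene
    may appear under several cell types.
    """
    markers: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need two columns (cell_type, gene)")
            cell_type, gene = fields[0], fields[1]
            n_rows += 1
            if (cell_type, gene) in seen:
                continue
            seen.add((cell_type, gene))
            markers.setdefault(cell_type, []).append(gene)
    if n_rows == 0:
        raise ValueError(f"empty signature file: {path}")
    return SignatureSet(markers)


def write_signatures(signatures: SignatureSet, path: str) -> None:
    with open(path, "w") as fh:
        for cell_type, genes in signatures.markers.items():
            for gene in genes:
                fh.write(f"{cell_type}\t{gene}\n")


def read_pwms(path: str) -> list[PWM]:
    """Read PWMs from '>name' headed blocks of 4-column count/frequency rows.

    Rows are normalized to probabilities; a row of all zeros or any
    negative entry is an error.
    """
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise ValueError(f"{path}: PWM {name} has no rows")
        mat = np.asarray(rows, dtype=float)
        if (mat < 0).any():
            raise ValueError(f"{path}: PWM {name} has a negative entry")
        sums = mat.sum(axis=1)
        if (sums <= 0).any():
            bad = int(np.argmax(sums <= 0)) + 1
            raise ValueError(f"{path}: PWM {name} row {bad} is all zeros")
        pwms.append(PWM(name, mat / sums[:, None]))
        name, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                continue
            if name is None:
                raise ValueError(f"{path}:{lineno}: data row before any '>' header")
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: PWM rows need 4 columns (ACGT)")
            rows.append([float(x) for x in fields])
    flush()
    return pwms


def write_pwms(pwms: list[PWM], path: str) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.probs:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")
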