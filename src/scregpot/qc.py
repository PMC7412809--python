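"""Single-cell barcode quality metrics and filtering, plus peak binarization.

RNA barcodes are scored from the gene-by-cell count matrix; ATAC barcodes
from a 10x-style fragments table against gene promoter windows.  Filtering
follows the literal threshold wording: "more than" is strict, "at least"
and "no more than" are non-strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .genome_io import GeneModel, GenomicInterval, NamedMatrix

__all__ = [
    "FragmentRecord",
    "CellQCMetrics",
    "QCThresholds",
    "RNA_QC_DEFAULTS",
    "ATAC_QC_DEFAULTS",
    "read_fragments",
    "write_fragments",
    "rna_cell_metrics",
    "atac_cell_metrics",
    "filter_cells",
    "binarize",
]


@dataclass(frozen=True)
class FragmentRecord:
    interval: GenomicInterval
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("fragment count must be >= 1")


@dataclass
class CellQCMetrics:
    barcode: str
    n_reads: int
    n_features: int = 0
    frac_promoter: float = 0.0
    frac_mito: float = 0.0
    frac_spikein: float = 0.0


@dataclass
class QCThresholds:
    """Barcode-passing thresholds.

    ``None`` disables a criterion (e.g. promoter fraction for RNA,
    feature count for ATAC).
    """

    min_reads: int = 1000            # strict: n_reads > min_reads
    min_features: int | None = None  # non-strict: n_features >= min_features
    min_frac_promoter: float | None = None
    max_frac_mito: float = 1.0
    max_frac_spikein: float = 1.0


RNA_QC_DEFAULTS = QCThresholds(
    min_reads=1000, min_features=500, min_frac_promoter=None,
    max_frac_mito=0.05, max_frac_spikein=0.05,
)
ATAC_QC_DEFAULTS = QCThresholds(
    min_reads=1000, min_features=None, min_frac_promoter=0.10,
    max_frac_mito=0.10, max_frac_spikein=1.0,
)


def read_fragments(path: str) -> list[FragmentRecord]:
    """Read a fragments TSV (chrom, start, end, barcode[, count])."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >=4 columns")
            count = int(fields[4]) if len(fields) > 4 else 1
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            records.append(FragmentRecord(iv, fields[3], count))
    return records


def write_fragments(records: Iterable[FragmentRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.barcode}\t{rec.count}\n")


def rna_cell_metrics(
    counts: NamedMatrix,
    mito_gene_prefix: str = "MT-",
    spikein_prefix: str = "ERCC-",
) -> list[CellQCMetrics]:
    """Per-barcode read/feature counts and mito / spike-in fractions.

    ``counts`` is genes x cells.  All-zero barcodes get zero fractions.
    """
    values = counts.values.tocsc() if sp.issparse(counts.values) else np.asarray(counts.values)
    genes = np.array(counts.row_names)
    mito_mask = np.char.startswith(genes.astype(str), mito_gene_prefix)
    spike_mask = np.char.startswith(genes.astype(str), spikein_prefix)

    if sp.issparse(values):
        col_sums = np.asarray(values.sum(axis=0)).ravel()
        n_feats = np.asarray((values > 0).sum(axis=0)).ravel()
        mito_sums = np.asarray(values[mito_mask.nonzero()[0]].sum(axis=0)).ravel()
        spike_sums = np.asarray(values[spike_mask.nonzero()[0]].sum(axis=0)).ravel()
    else:
        col_sums = values.sum(axis=0)
        n_feats = (values > 0).sum(axis=0)
        mito_sums = values[mito_mask].sum(axis=0)
        spike_sums = values[spike_mask].sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac_mito = np.where(col_sums > 0, mito_sums / np.maximum(col_sums, 1), 0.0)
        frac_spike = np.where(col_sums > 0, spike_sums / np.maximum(col_sums, 1), 0.0)

    return [
        CellQCMetrics(
            barcode=bc,
            n_reads=int(col_sums[j]),
            n_features=int(n_feats[j]),
            frac_mito=float(frac_mito[j]),
            frac_spikein=float(frac_spike[j]),
        )
        for j, bc in enumerate(counts.col_names)
    ]


def _promoter_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        prom = gene.promoter
        trees.setdefault(prom.chrom, IntervalTree()).addi(prom.start, prom.end)
    return trees


def atac_cell_metrics(
    fragments: list[FragmentRecord],
    genes: list[GeneModel],
    mito_chroms: set[str] = frozenset({"chrM", "MT"}),
) -> list[CellQCMetrics]:
    """Count-weighted per-barcode read totals, promoter and mito fractions.

    A fragment counts toward the promoter fraction if it overlaps any gene
    promoter window by at least one base.
    """
    trees = _promoter_trees(genes)
    totals: dict[str, int] = {}
    promoter: dict[str, int] = {}
    mito: dict[str, int] = {}
    order: list[str] = []
    for rec in fragments:
        bc = rec.barcode
        if bc not in totals:
            totals[bc] = promoter[bc] = mito[bc] = 0
            order.append(bc)
        totals[bc] += rec.count
        iv = rec.interval
        if iv.chrom in mito_chroms:
            mito[bc] += rec.count
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            promoter[bc] += rec.count
    out = []
    for bc in order:
        n = totals[bc]
        out.append(
            CellQCMetrics(
                barcode=bc,
                n_reads=n,
                frac_promoter=promoter[bc] / n if n else 0.0,
                frac_mito=mito[bc] / n if n else 0.0,
            )
        )
    return out


def filter_cells(
    metrics: list[CellQCMetrics], thresholds: QCThresholds
) -> set[str]:
    """Barcodes passing all enabled thresholds."""
    passing = set()
    for m in metrics:
        if m.n_reads <= thresholds.min_reads:
            continue
        if thresholds.min_features is not None and m.n_features < thresholds.min_features:
            continue
        if (
            thresholds.min_frac_promoter is not None
            and m.frac_promoter < thresholds.min_frac_promoter
        ):
            continue
        if m.frac_mito > thresholds.max_frac_mito:
            continue
        if m.frac_spikein > thresholds.max_frac_spikein:
            continue
        passing.add(m.barcode)
    return passing


def metrics_frame(metrics: list[CellQCMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": [m.barcode for m in metrics],
            "n_reads": [m.n_reads for m in metrics],
            "n_features": [m.n_features for m in metrics],
            "frac_promoter": [m.frac_promoter for m in metrics],
            "frac_mito": [m.frac_mito for m in metrics],
            "frac_spikein": [m.frac_spikein for m in metrics],
        }
    ).set_index("barcode")


def binarize(matrix: NamedMatrix) -> NamedMatrix:
    """Convert a nonnegative peak count matrix to a 0/1 occurrence matrix."""
    values = matrix.values
    if sp.issparse(values):
        if (values.data < 0).any():
            raise ValueError("negative entries cannot be binarized")
        out = values.copy().tocsr()
        out.data = (out.data > 0).astype(np.int8)
        out.eliminate_zeros()
    else:
        arr = np.asarray(values)
        if (arr < 0).any():
            raise ValueError("negative entries cannot be binarized")
        out = (arr > 0).astype(np.int8)
    return NamedMatrix(out, matrix.row_names, matrix.col_names)
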