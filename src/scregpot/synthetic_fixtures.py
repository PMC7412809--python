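"""Deterministic generator of coupled scRNA/scATAC toy datasets.

One synthetic chromosome carries non-overlapping genes, each with a
promoter peak at its TSS, an exonic peak, and a few distal peaks within
the regulatory-potential cutoff; background peaks sit beyond the cutoff
of every TSS.  Cell types differ in the accessibility of the peaks
linked to their marker genes, and RNA counts are drawn
negative-binomially around means proportional to the planted regulatory
potential of each type's open-peak profile — the coupling the RP model
assumes.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .genome_io import GeneModel, GenomicInterval, NamedMatrix, SignatureSet
from .qc import FragmentRecord
from .rp_model import RPConfig, build_weight_matrix

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "simulate_genome",
    "simulate_cells",
    "simulate_fragments",
]

CHROM = "chrS"
MITO_CHROM = "chrM"
GENE_SPACING = 60_000
GENE_LENGTH = 8_000
PEAK_WIDTH = 500
GENE_OFFSET = 40_000  # first TSS position; leaves room for upstream distal peaks


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    effect_size is the fold increase in open-peak probability for peaks
    linked to a cell type's marker genes (4 = strong signal); p_base /
    p_promoter are baseline open probabilities for distal-or-exonic and
    promoter peaks; rna_depth is the mean per-cell count total;
    nb_dispersion the negative-binomial overdispersion;
    cell_depth_factor scales every cell's open probabilities to emulate
    sequencing-depth titration.
    """

    n_genes: int = 150
    n_peaks: int = 2000
    n_cell_types: int = 4
    rna_cells_per_type: int = 100
    atac_cells_per_type: int = 100
    markers_per_type: int = 20
    effect_size: float = 4.0
    p_base: float = 0.25
    p_promoter: float = 0.8
    rna_depth: float = 5000.0
    nb_dispersion: float = 0.2
    cell_depth_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.n_cell_types * self.markers_per_type > self.n_genes:
            raise ValueError("not enough genes for the requested marker sets")
        for name in ("n_genes", "n_peaks", "n_cell_types", "rna_cells_per_type",
                     "atac_cells_per_type", "markers_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    peaks: list[GenomicInterval]
    peak_gene: list[int | None]   # index of the linked gene, None for background
    peak_kind: list[str]          # promoter | exon | distal | background


def _peak_at(center: int, used: set[int]) -> GenomicInterval:
    while center in used:
        center += 7
    used.add(center)
    half = PEAK_WIDTH // 2
    return GenomicInterval(CHROM, center - half, center + half)


def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Genes tiled on one chromosome plus promoter/exon/distal/background peaks."""
    rng = np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    peaks: list[GenomicInterval] = []
    peak_gene: list[int | None] = []
    peak_kind: list[str] = []
    used_centers: set[int] = set()

    for g in range(config.n_genes):
        tss = g * GENE_SPACING + GENE_OFFSET
        body = GenomicInterval(CHROM, tss, tss + GENE_LENGTH, "+")
        exons = [
            GenomicInterval(CHROM, tss, tss + 2000, "+"),
            GenomicInterval(CHROM, tss + 6000, tss + GENE_LENGTH, "+"),
        ]
        genes.append(GeneModel(f"G{g:04d}", f"G{g:04d}", body, exons))

        peaks.append(_peak_at(tss, used_centers))
        peak_gene.append(g)
        peak_kind.append("promoter")

        peaks.append(_peak_at(tss + 7000, used_centers))  # inside the second exon
        peak_gene.append(g)
        peak_kind.append("exon")

        for _ in range(int(rng.integers(1, 4))):  # 1-3 distal peaks within 150 kb
            if rng.random() < 0.5:
                offset = -int(rng.integers(3_000, 30_000))
            else:
                offset = int(rng.integers(10_000, 30_000))
            peaks.append(_peak_at(tss + offset, used_centers))
            peak_gene.append(g)
            peak_kind.append("distal")

    n_background = config.n_peaks - len(peaks)
    if n_background < 0:
        raise ValueError(
            f"n_peaks={config.n_peaks} too small for {len(peaks)} gene-linked peaks"
        )
    bg_start = (config.n_genes - 1) * GENE_SPACING + GENE_OFFSET + 151_000
    for b in range(n_background):
        peaks.append(_peak_at(bg_start + b * 2_000, used_centers))
        peak_gene.append(None)
        peak_kind.append("background")

    return SyntheticGenome(genes, peaks, peak_gene, peak_kind)


def _open_probabilities(config: SimulationConfig, genome: SyntheticGenome) -> np.ndarray:
    """Cell-type x peak matrix of open probabilities encoding the markers."""
    rng = np.random.default_rng(config.seed + 1)
    K = config.n_cell_types
    marker_genes = rng.permutation(config.n_genes)[: K * config.markers_per_type]
    marker_type = {}  # gene index -> cell type
    for t in range(K):
        for g in marker_genes[t * config.markers_per_type : (t + 1) * config.markers_per_type]:
            marker_type[int(g)] = t

    base = np.array(
        [config.p_promoter if kind == "promoter" else config.p_base for kind in genome.peak_kind]
    )
    probs = np.tile(base, (K, 1))
    for i, g in enumerate(genome.peak_gene):
        if g is None or g not in marker_type:
            continue
        t = marker_type[g]
        probs[t, i] = min(0.95, config.effect_size * base[i])
    return np.clip(probs * config.cell_depth_factor, 0.0, 0.95), marker_type


def simulate_cells(config: SimulationConfig, genome: SyntheticGenome):
    """Coupled RNA counts, ATAC binary matrix, true labels, and signatures.

    Returns (rna_counts, atac_binary, rna_types, atac_types, signatures)
    where the type dicts map barcode -> "TypeK".
    """
    rng = np.random.default_rng(config.seed + 2)
    probs, marker_type = _open_probabilities(config, genome)
    K = config.n_cell_types
    gene_names = [g.gene_id for g in genome.genes]
    peak_names = [f"{p.chrom}:{p.start}-{p.end}" for p in genome.peaks]

    # planted per-type regulatory potential from the expected open profile,
    # under the package's default (enhanced) model
    W = build_weight_matrix(genome.peaks, genome.genes, RPConfig()).values.toarray()
    planted_rp = probs @ W  # K x genes

    atac_cols, atac_types = [], {}
    atac_blocks = []
    for t in range(K):
        block = (
            rng.random((config.atac_cells_per_type, len(genome.peaks))) < probs[t]
        ).astype(np.int8)
        atac_blocks.append(block)
        for i in range(config.atac_cells_per_type):
            bc = f"ATAC_T{t}_{i:04d}"
            atac_cols.append(bc)
            atac_types[bc] = f"Type{t}"
    atac_binary = NamedMatrix(
        sp.csr_matrix(np.vstack(atac_blocks).T), peak_names, atac_cols
    )

    rna_cols, rna_types = [], {}
    rna_blocks = []
    for t in range(K):
        rp = planted_rp[t]
        mean = config.rna_depth * rp / rp.sum()
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, np.tile(mean, (config.rna_cells_per_type, 1)) / shape)
        block = rng.poisson(lam)
        rna_blocks.append(block)
        for i in range(config.rna_cells_per_type):
            bc = f"RNA_T{t}_{i:04d}"
            rna_cols.append(bc)
            rna_types[bc] = f"Type{t}"
    rna_counts = NamedMatrix(
        sp.csr_matrix(np.vstack(rna_blocks).T), gene_names, rna_cols
    )

    signatures = SignatureSet(
        {
            f"Type{t}": [gene_names[g] for g, tt in sorted(marker_type.items()) if tt == t]
            for t in range(K)
        }
    )
    return rna_counts, atac_binary, rna_types, atac_types, signatures


def simulate_fragments(
    config: SimulationConfig,
    atac_binary: NamedMatrix,
    genome: SyntheticGenome,
    n_bad_low_count: int = 3,
    n_bad_low_promoter: int = 3,
    n_bad_high_mito: int = 3,
):
    """Fragment records for every cell plus planted low-quality barcodes.

    Good barcodes emit 1-3 fragments per open peak; planted bad barcodes
    violate exactly one of the default ATAC thresholds (unique-read count,
    promoter fraction, or mitochondrial fraction).  Returns
    (fragments, manifest) with manifest mapping barcode -> "good" or the
    planted failure mode.
    """
    rng = np.random.default_rng(config.seed + 3)
    fragments: list[FragmentRecord] = []
    manifest: dict[str, str] = {}
    B = atac_binary.values.tocsc() if sp.issparse(atac_binary.values) else sp.csc_matrix(atac_binary.values)
    promoter_mask = np.array([k == "promoter" for k in genome.peak_kind])
    non_promoter_idx = np.flatnonzero(~promoter_mask)

    def emit(peak: GenomicInterval, barcode: str, n: int) -> None:
        for _ in range(n):
            start = int(rng.integers(peak.start, peak.end - 100))
            fragments.append(FragmentRecord(GenomicInterval(peak.chrom, start, start + 100), barcode, 1))

    for j, barcode in enumerate(atac_binary.col_names):
        open_peaks = B.indices[B.indptr[j] : B.indptr[j + 1]]
        for i in open_peaks:
            emit(genome.peaks[int(i)], barcode, int(rng.integers(1, 4)))
        manifest[barcode] = "good"

    n_reads_typical = max(1200, int(2 * B.getnnz() / max(1, B.shape[1])))
    for b in range(n_bad_low_count):
        bc = f"BAD_LOWCOUNT_{b:02d}"
        for i in rng.integers(0, len(genome.peaks), size=300):
            emit(genome.peaks[int(i)], bc, 1)
        manifest[bc] = "low_count"
    for b in range(n_bad_low_promoter):
        bc = f"BAD_LOWPROM_{b:02d}"
        for i in rng.choice(non_promoter_idx, size=n_reads_typical):
            emit(genome.peaks[int(i)], bc, 1)
        manifest[bc] = "low_promoter"
    for b in range(n_bad_high_mito):
        bc = f"BAD_HIGHMITO_{b:02d}"
        for i in rng.integers(0, len(genome.peaks), size=n_reads_typical):
            if rng.random() < 0.3:
                start = int(rng.integers(0, 16_000))
                fragments.append(
                    FragmentRecord(GenomicInterval(MITO_CHROM, start, start + 100), bc, 1)
                )
            else:
                emit(genome.peaks[int(i)], bc, 1)
        manifest[bc] = "high_mito"
    return fragments, manifest
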