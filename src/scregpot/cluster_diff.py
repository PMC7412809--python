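"""Normalization, feature selection, LSI/PCA embedding, graph clustering,
and one-vs-rest Wilcoxon differential analysis.

Expression is depth-normalized to 10,000 counts per cell and
log-transformed; binary peak matrices are depth-weighted by the per-cell
open-peak count.  The scATAC embedding is TF-IDF followed by truncated
SVD (LSI, 50 dimensions); clustering builds a kNN graph with
Jaccard-refined edge weights and optimizes modularity at resolution 0.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg
import scipy.special
import scipy.stats
from sklearn.neighbors import NearestNeighbors

from .genome_io import NamedMatrix

__all__ = [
    "Embedding",
    "ClusterLabels",
    "MarkerRecord",
    "GENE_MARKER_THRESHOLDS",
    "PEAK_MARKER_THRESHOLDS",
    "normalize_log",
    "normalize_peak_depth",
    "select_variable_genes",
    "lsi_embed",
    "pca_embed",
    "cluster_cells",
    "wilcoxon_markers",
    "markers_frame",
]


@dataclass
class Embedding:
    """Cells x k coordinates with a method tag (lsi | pca | cca)."""

    coords: np.ndarray
    cell_names: list[str]
    method: str = "lsi"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValueError("embedding needs >= 2 dimensions")
        if self.coords.shape[0] != len(self.cell_names):
            raise ValueError("coordinate rows must match cell names")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding has non-finite entries")


@dataclass
class ClusterLabels:
    """Barcode -> cluster id mapping."""

    labels: dict[str, int]

    @classmethod
    def from_arrays(cls, barcodes, ids) -> "ClusterLabels":
        return cls(dict(zip(barcodes, (int(i) for i in ids))))

    def ids_for(self, barcodes) -> np.ndarray:
        return np.array([self.labels[b] for b in barcodes])

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.labels.values()))

    def members(self, cluster: int) -> list[str]:
        return [b for b, c in self.labels.items() if c == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"barcode": list(self.labels), "cluster": list(self.labels.values())}
        ).set_index("barcode")


@dataclass
class MarkerRecord:
    feature: str
    cluster: int
    logFC: float
    pct_in: float
    pct_out: float
    p_value: float


GENE_MARKER_THRESHOLDS = {"min_logfc": 0.25, "min_pct": 0.25, "max_p": 1e-5}
PEAK_MARKER_THRESHOLDS = {"min_logfc": 0.1, "min_pct": 0.01, "max_p": 1e-5}


def _col_normalize(values, scale_to=None):
    """Divide each column by its sum (optionally times a scale); zero columns stay zero."""
    if sp.issparse(values):
        colsum = np.asarray(values.sum(axis=0)).ravel()
        inv = np.divide(1.0, colsum, out=np.zeros_like(colsum, dtype=float), where=colsum > 0)
        if scale_to is not None:
            inv = inv * scale_to
        return values @ sp.diags(inv)
    arr = np.asarray(values, dtype=float)
    colsum = arr.sum(axis=0)
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    if scale_to is not None:
        inv = inv * scale_to
    return arr * inv


def normalize_log(counts: NamedMatrix, scale: float = 10_000.0) -> NamedMatrix:
    """Global-scaling normalization: x -> ln(1 + scale * x / colsum)."""
    scaled = _col_normalize(counts.values, scale_to=scale)
    if sp.issparse(scaled):
        out = scaled.tocsr()
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(scaled)
    return NamedMatrix(out, counts.row_names, counts.col_names)


def normalize_peak_depth(B: NamedMatrix) -> NamedMatrix:
    """Weight each cell's binary peak vector by its open-peak count."""
    return NamedMatrix(_col_normalize(B.values), B.row_names, B.col_names)


def select_variable_genes(normed: NamedMatrix, n: int = 2000) -> list[str]:
    """Top-n genes by standardized variance (variance-stabilizing selection).

    Fits a mean-variance trend in log10 space, standardizes each gene by
    its expected standard deviation, clips z-scores at sqrt(n_cells), and
    ranks genes by the variance of the clipped values.
    """
    X = normed.dense().astype(float)
    n_cells = X.shape[1]
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1) if n_cells > 1 else np.zeros_like(mean)

    usable = (mean > 0) & (var > 0)
    std_var = np.zeros(len(mean))
    if usable.sum() >= 3:
        logm, logv = np.log10(mean[usable]), np.log10(var[usable])
        deg = 2 if usable.sum() >= 6 else 1
        coef = np.polyfit(logm, logv, deg)
        expected_sd = np.sqrt(10 ** np.polyval(coef, np.log10(np.maximum(mean, 1e-12))))
        clip = np.sqrt(n_cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = (X - mean[:, None]) / expected_sd[:, None]
        Z = np.clip(np.nan_to_num(Z, nan=0.0, posinf=0.0, neginf=0.0), -clip, clip)
        std_var = Z.var(axis=1, ddof=1)
    std_var[~usable] = 0.0  # constant genes never selected

    n_available = int((std_var > 0).sum())
    if n > n_available:
        warnings.warn(
            f"requested {n} variable genes but only {n_available} have "
            "nonzero variance; returning all ranked genes"
        )
    order = np.lexsort((np.array(normed.row_names), -std_var))
    ranked = [normed.row_names[i] for i in order if std_var[i] > 0]
    return ranked[:n]


def _tfidf(B: NamedMatrix):
    """TF (entry / column sum) times IDF = ln(1 + n_cells / peak occurrence)."""
    values = B.values.tocsr() if sp.issparse(B.values) else sp.csr_matrix(np.asarray(B.values, float))
    n_cells = values.shape[1]
    tf = _col_normalize(values)
    occurrence = np.asarray((values > 0).sum(axis=1)).ravel()
    idf = np.log1p(np.divide(n_cells, occurrence, out=np.zeros(len(occurrence)), where=occurrence > 0))
    return sp.diags(idf) @ tf


def lsi_embed(B: NamedMatrix, k: int = 50, seed: int = 2020) -> Embedding:
    """TF-IDF + rank-k truncated SVD; coordinates = right singular vectors x values."""
    X = _tfidf(B)
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be smaller than both matrix dimensions {X.shape}")
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(X.shape))
    U, S, Vt = scipy.sparse.linalg.svds(X, k=k, v0=v0)
    order = np.argsort(S)[::-1]
    coords = (Vt[order].T) * S[order]
    return Embedding(coords, list(B.col_names), method="lsi")


def pca_embed(normed: NamedMatrix, genes: list[str] | None = None, k: int = 15) -> Embedding:
    """Scale selected genes to zero mean / unit variance, then rank-k PCA."""
    mat = normed.subset_rows(genes) if genes is not None else normed
    X = mat.dense().astype(float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.divide(X - mean, sd, out=np.zeros_like(X), where=sd > 0)
    if k >= min(Z.shape):
        raise ValueError(f"k={k} must be smaller than both matrix dimensions {Z.shape}")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    coords = Vt[:k].T * S[:k]
    return Embedding(coords, list(normed.col_names), method="pca")


def _jaccard_knn_graph(coords: np.ndarray, n_neighbors: int) -> ig.Graph:
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_sets = [set(row) for row in idx]  # includes self
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union if union else 0.0
            if w > 0:
                edges.append(key)
                weights.append(w)
    graph = ig.Graph(n=n, edges=edges)
    graph.es["weight"] = weights
    return graph


def cluster_cells(
    emb: Embedding,
    n_neighbors: int = 20,
    resolution: float = 0.6,
    seed: int = 2020,
) -> ClusterLabels:
    """Jaccard-refined kNN graph + modularity community detection (Leiden)."""
    n = emb.coords.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} cells, got {n}")
    graph = _jaccard_knn_graph(emb.coords, n_neighbors)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return ClusterLabels.from_arrays(emb.cell_names, partition.membership)


def _log_fold_change(delogged: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    mean_in = delogged[:, in_mask].mean(axis=1)
    mean_out = delogged[:, ~in_mask].mean(axis=1)
    return np.log((mean_in + 1.0) / (mean_out + 1.0))


def wilcoxon_markers(
    normed: NamedMatrix,
    labels: ClusterLabels,
    thresholds: dict | None = None,
    delog: bool = True,
) -> list[MarkerRecord]:
    """One-vs-rest two-sided Wilcoxon rank-sum markers per cluster.

    p-values use the tie-corrected normal approximation.  logFC is
    ln((mean_in + 1) / (mean_out + 1)) computed on de-logged normalized
    values (set ``delog=False`` for matrices not on a log scale).
    Features must satisfy logFC > min_logfc, pct_in >= min_pct, and
    p < max_p; clusters with fewer than 3 cells are skipped.
    """
    thr = dict(GENE_MARKER_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    X = normed.dense().astype(float)
    delogged = np.expm1(X) if delog else X
    cluster_of = labels.ids_for(normed.col_names)

    records: list[MarkerRecord] = []
    for cluster in sorted(set(cluster_of)):
        in_mask = cluster_of == cluster
        if in_mask.sum() < 3 or (~in_mask).sum() < 1:
            warnings.warn(f"cluster {cluster} has fewer than 3 cells; skipped")
            continue
        # exact enumeration when the group split is small enough; the
        # tie-corrected normal approximation otherwise
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if scipy.special.comb(n_in + n_out, n_in) <= 20_000:
            method = scipy.stats.PermutationMethod(n_resamples=20_001, rng=0)
        else:
            method = "asymptotic"
        with np.errstate(all="ignore"):
            res = scipy.stats.mannwhitneyu(
                X[:, in_mask], X[:, ~in_mask], axis=1,
                alternative="two-sided", method=method,
            )
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        logfc = _log_fold_change(delogged, in_mask)
        pct_in = (X[:, in_mask] > 0).mean(axis=1)
        pct_out = (X[:, ~in_mask] > 0).mean(axis=1)
        keep = (logfc > thr["min_logfc"]) & (pct_in >= thr["min_pct"]) & (pvals < thr["max_p"])
        for i in np.flatnonzero(keep):
            records.append(
                MarkerRecord(
                    feature=normed.row_names[i],
                    cluster=int(cluster),
                    logFC=float(logfc[i]),
                    pct_in=float(pct_in[i]),
                    pct_out=float(pct_out[i]),
                    p_value=float(pvals[i]),
                )
            )
    return records


def markers_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in records],
            "cluster": [r.cluster for r in records],
            "logFC": [r.logFC for r in records],
            "pct_in": [r.pct_in for r in records],
            "pct_out": [r.pct_out for r in records],
            "p_value": [r.p_value for r in records],
        }
    )
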