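"""Cross-modality integration and the evaluation statistics.

scRNA and scATAC cells are co-embedded by a CCA-style SVD of the
cross-product of their standardized shared-gene matrices; mutual nearest
neighbors in the joint space form anchors, and cluster or cell-type
labels flow from RNA to ATAC cells through Gaussian-kernel-weighted
anchor votes.  The module also implements the benchmark statistics:
NMI, Gini / RAGI, median F1, and per-cell-type expression-activity
Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import sklearn.metrics
from sklearn.neighbors import NearestNeighbors

from .cluster_diff import ClusterLabels, Embedding
from .genome_io import NamedMatrix

__all__ = [
    "AnchorSet",
    "TransferResult",
    "cca_embed",
    "find_anchors",
    "transfer_labels",
    "nmi",
    "gini",
    "ragi",
    "median_f1",
    "expression_activity_correlation",
]

UNASSIGNED = "unassigned"
PREDICTION_SCORE_CUTOFF = 0.5  # max_score above this marks a high-quality transfer


@dataclass
class Anchor:
    rna_cell: str
    atac_cell: str
    weight: float


@dataclass
class AnchorSet:
    anchors: list[Anchor]
    embedding: "JointEmbedding"

    def __len__(self) -> int:
        return len(self.anchors)

    def pairs(self) -> set[tuple[str, str]]:
        return {(a.rna_cell, a.atac_cell) for a in self.anchors}


@dataclass
class JointEmbedding:
    """CCA coordinates for both modalities in a shared k-dimensional space."""

    rna: Embedding
    atac: Embedding


@dataclass
class TransferResult:
    predictions: dict[str, str]
    scores: dict[str, dict[str, float]]

    def max_scores(self) -> dict[str, float]:
        return {
            cell: max(s.values()) if s else 0.0 for cell, s in self.scores.items()
        }

    def to_frame(self) -> pd.DataFrame:
        max_s = self.max_scores()
        return pd.DataFrame(
            {
                "barcode": list(self.predictions),
                "predicted_label": list(self.predictions.values()),
                "max_score": [max_s[c] for c in self.predictions],
            }
        ).set_index("barcode")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return np.divide(X - mean, sd, out=np.zeros_like(X), where=sd > 0)


def cca_embed(X: NamedMatrix, Y: NamedMatrix, k: int = 20) -> JointEmbedding:
    """Joint embedding from the rank-k SVD of XᵀY over shared genes.

    ``X`` (expression) and ``Y`` (gene activity) must carry identical gene
    rows.  Gene rows are standardized within each modality; RNA cells take
    the left singular vectors and ATAC cells the right ones, each row
    L2-normalized.
    """
    if X.row_names != Y.row_names:
        raise ValueError("X and Y must share the same gene rows in the same order")
    if len(X.row_names) < k:
        raise ValueError(f"need at least k={k} shared genes, got {len(X.row_names)}")
    Xs = _standardize_rows(X.dense().astype(float))
    Ys = _standardize_rows(Y.dense().astype(float))
    K = Xs.T @ Ys  # rna cells x atac cells
    U, S, Vt = np.linalg.svd(K, full_matrices=False)
    U, V = U[:, :k], Vt[:k].T

    def l2(rows: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        return np.divide(rows, norms, out=np.zeros_like(rows), where=norms > 0)

    return JointEmbedding(
        rna=Embedding(l2(U), list(X.col_names), method="cca"),
        atac=Embedding(l2(V), list(Y.col_names), method="cca"),
    )


def find_anchors(emb: JointEmbedding, k_anchor: int = 5) -> AnchorSet:
    """Mutual-nearest-neighbor anchor pairs across modalities.

    (r, a) is an anchor iff a is among r's k nearest ATAC cells and r is
    among a's k nearest RNA cells; the weight is 1 minus the mean
    0-based rank fraction of the pair within the two neighbor lists.
    """
    R, A = emb.rna.coords, emb.atac.coords
    k_r = min(k_anchor, len(A))
    k_a = min(k_anchor, len(R))
    nn_atac = NearestNeighbors(n_neighbors=k_r).fit(A)
    _, rna_to_atac = nn_atac.kneighbors(R)
    nn_rna = NearestNeighbors(n_neighbors=k_a).fit(R)
    _, atac_to_rna = nn_rna.kneighbors(A)

    rank_in_rna_list = {
        (r, int(a)): pos for r in range(len(R)) for pos, a in enumerate(rna_to_atac[r])
    }
    anchors = []
    for a in range(len(A)):
        for pos_a, r in enumerate(atac_to_rna[a]):
            pos_r = rank_in_rna_list.get((int(r), a))
            if pos_r is None:
                continue
            rank_fraction = (pos_r / k_r + pos_a / k_a) / 2.0
            anchors.append(
                Anchor(emb.rna.cell_names[int(r)], emb.atac.cell_names[a], 1.0 - rank_fraction)
            )
    return AnchorSet(anchors, emb)


def transfer_labels(
    anchors: AnchorSet,
    rna_labels: dict[str, str] | ClusterLabels,
    k_weight: int = 20,
) -> TransferResult:
    """Transfer RNA labels to ATAC cells via Gaussian-kernel anchor votes.

    Each ATAC cell's ``k_weight`` nearest anchors (distance measured to
    the anchor's ATAC-side coordinate) vote with weight
    anchor_weight x exp(-d² / (2σ²)), σ set to the neighborhood's largest
    distance; votes per label are normalized to sum to 1.  Cells with no
    reachable anchor are labeled "unassigned" with score 0.
    """
    if isinstance(rna_labels, ClusterLabels):
        rna_labels = {b: str(c) for b, c in rna_labels.labels.items()}
    emb = anchors.embedding
    atac_names = emb.atac.cell_names
    predictions: dict[str, str] = {}
    scores: dict[str, dict[str, float]] = {}
    if not anchors.anchors:
        return TransferResult(
            {c: UNASSIGNED for c in atac_names}, {c: {} for c in atac_names}
        )

    atac_index = {name: i for i, name in enumerate(atac_names)}
    anchor_coords = np.array(
        [emb.atac.coords[atac_index[a.atac_cell]] for a in anchors.anchors]
    )
    anchor_weights = np.array([a.weight for a in anchors.anchors])
    anchor_labels = [rna_labels[a.rna_cell] for a in anchors.anchors]

    k = min(k_weight, len(anchors.anchors))
    nn = NearestNeighbors(n_neighbors=k).fit(anchor_coords)
    dists, idx = nn.kneighbors(emb.atac.coords)
    for i, cell in enumerate(atac_names):
        d = dists[i]
        sigma = d.max() if d.max() > 0 else 1.0
        kernel = np.exp(-(d ** 2) / (2 * sigma ** 2))
        votes: dict[str, float] = {}
        for w, j in zip(kernel * anchor_weights[idx[i]], idx[i]):
            votes[anchor_labels[j]] = votes.get(anchor_labels[j], 0.0) + float(w)
        total = sum(votes.values())
        if total <= 0:
            predictions[cell] = UNASSIGNED
            scores[cell] = {}
            continue
        normalized = {lab: v / total for lab, v in votes.items()}
        scores[cell] = normalized
        predictions[cell] = min(normalized, key=lambda l: (-normalized[l], l))
    return TransferResult(predictions, scores)


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------

def _as_arrays(labels_a, labels_b):
    if isinstance(labels_a, ClusterLabels) and isinstance(labels_b, ClusterLabels):
        barcodes = sorted(set(labels_a.labels) & set(labels_b.labels))
        return labels_a.ids_for(barcodes), labels_b.ids_for(barcodes)
    a = np.asarray(list(labels_a))
    b = np.asarray(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    return a, b


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    a, b = _as_arrays(labels_a, labels_b)
    return float(
        sklearn.metrics.normalized_mutual_info_score(a, b, average_method="arithmetic")
    )


def gini(values) -> float:
    """Discrete Gini of a nonnegative vector: Σ_ij |x_i - x_j| / (2 n Σx)."""
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("Gini requires nonnegative values")
    total = x.sum()
    if total == 0 or len(x) < 2:
        return 0.0
    xs = np.sort(x)
    n = len(xs)
    # sum_ij |xi - xj| = 2 * sum_i (2i - n + 1) * x_(i)   (0-based i)
    abs_sum = 2.0 * np.sum((2 * np.arange(n) - n + 1) * xs)
    return float(abs_sum / (2 * n * total))


def _per_cluster_means(activity: NamedMatrix, labels: ClusterLabels) -> pd.DataFrame:
    X = activity.dense().astype(float)
    cluster_of = labels.ids_for(activity.col_names)
    out = {
        c: X[:, cluster_of == c].mean(axis=1) for c in sorted(set(cluster_of))
    }
    return pd.DataFrame(out, index=activity.row_names)


def ragi(
    activity: NamedMatrix,
    labels: ClusterLabels,
    markers,
    housekeeping,
) -> float:
    """Residual average Gini index: mean marker Gini minus mean housekeeping Gini.

    The Gini of each gene is computed over its per-cluster mean activity.
    """
    means = _per_cluster_means(activity, labels)
    def mean_gini(genes) -> float:
        present = [g for g in genes if g in means.index]
        if not present:
            return 0.0
        return float(np.mean([gini(means.loc[g].to_numpy()) for g in present]))
    return mean_gini(markers) - mean_gini(housekeeping)


def median_f1(true_labels, predicted_labels) -> float:
    """Median over true classes of the per-class F1 = 2PR/(P+R)."""
    y_true = np.asarray(list(true_labels))
    y_pred = np.asarray(list(predicted_labels))
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    classes = sorted(set(y_true))
    f1 = sklearn.metrics.f1_score(
        y_true, y_pred, labels=classes, average=None, zero_division=0
    )
    return float(np.median(f1))


def expression_activity_correlation(
    expr: NamedMatrix,
    activity: NamedMatrix,
    rna_types: dict[str, str],
    atac_types: dict[str, str],
    genes: list[str] | None = None,
) -> dict[str, float]:
    """Per-cell-type Spearman rho between mean expression and mean activity.

    Cells of each modality are grouped by their cell-type label; profiles
    are averaged over the group and correlated over ``genes`` (default:
    all shared genes).
    """
    shared = genes if genes is not None else [
        g for g in expr.row_names if g in set(activity.row_names)
    ]
    E = expr.subset_rows(shared).dense().astype(float)
    A = activity.subset_rows(shared).dense().astype(float)
    rna_of = np.array([rna_types[c] for c in expr.col_names])
    atac_of = np.array([atac_types[c] for c in activity.col_names])
    out = {}
    for cell_type in sorted(set(rna_of) & set(atac_of)):
        e = E[:, rna_of == cell_type].mean(axis=1)
        a = A[:, atac_of == cell_type].mean(axis=1)
        rho = scipy.stats.spearmanr(e, a).statistic
        out[cell_type] = float(rho)
    return out
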