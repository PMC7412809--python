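"""Automatic cell-type annotation of clusters from marker-gene logFC.

For each cluster the score of a signature is the summed log fold change
of its marker genes (cluster vs all other cells) divided by log2 of the
marker count; the highest-scoring signature names the cluster, and a
cluster where every signature scores <= 0 is left as "others".  The same
procedure runs on log-normalized expression or gene-activity input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_diff import ClusterLabels, _log_fold_change
from .genome_io import NamedMatrix, SignatureSet

__all__ = [
    "ClusterAnnotation",
    "cluster_logfc",
    "signature_score",
    "assign_cell_types",
    "annotate_clusters",
]

OTHERS = "others"


@dataclass
class ClusterAnnotation:
    cluster: int
    cell_type: str
    score: float
    per_type_scores: dict[str, float] = field(default_factory=dict)


def cluster_logfc(normed: NamedMatrix, labels: ClusterLabels, delog: bool = True) -> pd.DataFrame:
    """Genes x clusters logFC matrix (no significance filtering).

    Same formula as the marker test: ln((mean_in + 1)/(mean_out + 1)) on
    de-logged values; negative values are kept.
    """
    X = normed.dense().astype(float)
    delogged = np.expm1(X) if delog else X
    cluster_of = labels.ids_for(normed.col_names)
    clusters = sorted(set(cluster_of))
    out = {}
    for cluster in clusters:
        in_mask = cluster_of == cluster
        if (~in_mask).sum() == 0:
            out[cluster] = np.zeros(X.shape[0])
            continue
        out[cluster] = _log_fold_change(delogged, in_mask)
    return pd.DataFrame(out, index=normed.row_names)


def signature_score(logfc_col: pd.Series, signatures: SignatureSet) -> dict[str, float]:
    """Per-type score: sum of marker logFC / log2(max(2, #present markers)).

    Markers are intersected with the genes present in the matrix; a type
    with no present marker scores -inf and can never be selected.
    """
    present = set(logfc_col.index)
    scores: dict[str, float] = {}
    for cell_type, markers in signatures.markers.items():
        found = [g for g in markers if g in present]
        if not found:
            warnings.warn(f"signature {cell_type!r} has no markers in the data")
            scores[cell_type] = -math.inf
            continue
        total = float(logfc_col.loc[found].sum())
        scores[cell_type] = total / math.log2(max(2, len(found)))
    return scores


def assign_cell_types(scores_per_cluster: dict[int, dict[str, float]]) -> list[ClusterAnnotation]:
    """Argmax with lexicographic tie-break; max <= 0 -> "others"."""
    annotations = []
    for cluster in sorted(scores_per_cluster):
        scores = scores_per_cluster[cluster]
        best_type = min(
            scores, key=lambda t: (-scores[t], t)
        )  # highest score, ties by name
        best = scores[best_type]
        if not (best > 0):
            annotations.append(ClusterAnnotation(cluster, OTHERS, best, dict(scores)))
        else:
            annotations.append(ClusterAnnotation(cluster, best_type, best, dict(scores)))
    return annotations


def annotate_clusters(
    normed: NamedMatrix,
    labels: ClusterLabels,
    signatures: SignatureSet,
    delog: bool = True,
) -> list[ClusterAnnotation]:
    """End-to-end: cluster logFC -> signature scores -> assignments."""
    logfc = cluster_logfc(normed, labels, delog=delog)
    scores = {
        int(cluster): signature_score(logfc[cluster], signatures)
        for cluster in logfc.columns
    }
    return assign_cell_types(scores)


def annotations_frame(annotations: list[ClusterAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster": [a.cluster for a in annotations],
            "cell_type": [a.cell_type for a in annotations],
            "score": [a.score for a in annotations],
        }
    ).set_index("cluster")
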