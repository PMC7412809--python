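"""Driver-regulator inference from cluster-specific peaks.

Enrichment of each regulator's reference peak set in a cluster's specific
peaks is scored with a composite statistic, -log10(p) x log2(odds ratio),
from a one-sided Fisher exact test over the peak universe.  Regulators
whose binding motifs form a family (PWM similarity > 0.7 under an
information-content-weighted Pearson correlation) share their best score,
rankings from expression and accessibility are combined by rank product,
and regulators with no expression or low regulatory potential are
filtered out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from intervaltree import IntervalTree

from .genome_io import GenomicInterval, PWM

__all__ = [
    "EnrichmentRecord",
    "MotifFamily",
    "pwm_similarity",
    "cluster_motifs",
    "peakset_enrichment",
    "propagate_family_scores",
    "rank_product_combine",
    "filter_regulators",
    "enrichment_frame",
]

TOP_REGULATORS = 100  # per-cluster output truncation


@dataclass
class EnrichmentRecord:
    regulator: str
    cluster: int | str
    p_value: float
    odds_ratio: float
    score: float
    rank: int = 0


@dataclass
class MotifFamily:
    family_id: int
    members: list[str] = field(default_factory=list)


def _column_pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two 4-probability columns; 0 if either is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (4 * sa * sb))


def _ic(col: np.ndarray) -> float:
    plogp = np.where(col > 0, col * np.log2(np.maximum(col, 1e-300)), 0.0)
    return 2.0 + float(plogp.sum())


def _aligned_similarity(a: PWM, b: PWM, min_overlap: int) -> float:
    """IC-weighted mean column PCC, maximized over alignment offsets."""
    la, lb = a.length, b.length
    best = -np.inf
    # offset = position of b's first column relative to a's first column
    for offset in range(-(lb - min_overlap), la - min_overlap + 1):
        lo = max(0, offset)
        hi = min(la, offset + lb)
        if hi - lo < min_overlap:
            continue
        num = den = 0.0
        for k in range(lo, hi):
            ca, cb = a.probs[k], b.probs[k - offset]
            w = (_ic(ca) + _ic(cb)) / 2.0
            num += w * _column_pcc(ca, cb)
            den += w
        if den > 0:
            best = max(best, num / den)
    return best


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = 5) -> float:
    """Maximum IC-weighted Pearson similarity over offsets and strands, in [-1, 1]."""
    if min(a.length, b.length) < min_overlap:
        raise ValueError(
            f"PWMs of length {a.length} and {b.length} cannot overlap by {min_overlap}"
        )
    forward = _aligned_similarity(a, b, min_overlap)
    reverse = _aligned_similarity(a, b.reverse_complement(), min_overlap)
    best = max(forward, reverse)
    return float(np.clip(best, -1.0, 1.0))


def cluster_motifs(pwms: list[PWM], threshold: float = 0.7, min_overlap: int = 5) -> list[MotifFamily]:
    """Average-linkage hierarchical families cut at distance 1 - threshold."""
    n = len(pwms)
    if n == 0:
        return []
    if n == 1:
        return [MotifFamily(1, [pwms[0].name])]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = max(0.0, 1.0 - pwm_similarity(pwms[i], pwms[j], min_overlap))
            dist[i, j] = dist[j, i] = d
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    linkage = scipy.cluster.hierarchy.linkage(condensed, method="average")
    assignments = scipy.cluster.hierarchy.fcluster(
        linkage, t=1.0 - threshold, criterion="distance"
    )
    families: dict[int, list[str]] = {}
    for pwm, fam in zip(pwms, assignments):
        families.setdefault(int(fam), []).append(pwm.name)
    return [MotifFamily(fam, members) for fam, members in sorted(families.items())]


def _overlap_mask(
    universe: list[GenomicInterval], reference: list[GenomicInterval]
) -> np.ndarray:
    trees: dict[str, IntervalTree] = {}
    for iv in reference:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    mask = np.zeros(len(universe), dtype=bool)
    for i, iv in enumerate(universe):
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            mask[i] = True
    return mask


def composite_score(p_value: float, odds_ratio: float) -> float:
    """-log10(p) x log2(OR); negative under depletion (OR < 1)."""
    p = max(p_value, 1e-300)
    return -math.log10(p) * math.log2(odds_ratio)


def peakset_enrichment(
    cluster_peaks: list[GenomicInterval],
    universe: list[GenomicInterval],
    reference_sets: dict[str, list],
    cluster: int | str = 0,
) -> list[EnrichmentRecord]:
    """Fisher-exact enrichment of reference peak sets in cluster peaks.

    The 2x2 table counts universe peaks by (in cluster) x (overlaps the
    reference set).  p is the one-sided Fisher exact enrichment tail on
    the raw counts; the odds ratio uses Haldane +0.5 smoothing so it is
    defined with zero cells.  A regulator mapped to several reference
    sets keeps only its best-scoring one.  Each query peak counts once
    however many reference peaks hit it.
    """
    if not universe:
        raise ValueError("empty peak universe")
    key = lambda iv: (iv.chrom, iv.start, iv.end)
    universe_keys = {key(iv): i for i, iv in enumerate(universe)}
    in_cluster = np.zeros(len(universe), dtype=bool)
    for iv in cluster_peaks:
        idx = universe_keys.get(key(iv))
        if idx is None:
            raise ValueError(f"cluster peak {key(iv)} not in universe")
        in_cluster[idx] = True

    records = []
    for regulator, sets in reference_sets.items():
        if sets and isinstance(sets[0], GenomicInterval):
            sets = [sets]
        best = None
        for ref in sets:
            hits = _overlap_mask(universe, ref)
            a = int((in_cluster & hits).sum())
            b = int((in_cluster & ~hits).sum())
            c = int((~in_cluster & hits).sum())
            d = int((~in_cluster & ~hits).sum())
            _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            # score magnitude from the tail matching the direction of effect,
            # so depletion carries a negative score instead of collapsing to 0
            if odds >= 1.0:
                p_dir = p
            else:
                _, p_dir = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="less")
            score = composite_score(float(p_dir), odds)
            if best is None or score > best.score:
                best = EnrichmentRecord(regulator, cluster, float(p), odds, score)
        if best is not None:
            records.append(best)
    return _rerank(records)


def _rerank(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Rank 1 = highest score; ties broken by regulator name."""
    ordered = sorted(records, key=lambda r: (-r.score, r.regulator))
    for rank, rec in enumerate(ordered, start=1):
        rec.rank = rank
    return ordered


def propagate_family_scores(
    records: list[EnrichmentRecord], families: list[MotifFamily]
) -> list[EnrichmentRecord]:
    """Give every family member the family's best score; recompute ranks."""
    family_of: dict[str, int] = {}
    for fam in families:
        for member in fam.members:
            family_of[member] = fam.family_id
    best_in_family: dict[int, float] = {}
    for rec in records:
        fam = family_of.get(rec.regulator)
        if fam is not None:
            best_in_family[fam] = max(best_in_family.get(fam, -math.inf), rec.score)
    out = []
    for rec in records:
        fam = family_of.get(rec.regulator)
        score = best_in_family.get(fam, rec.score) if fam is not None else rec.score
        out.append(
            EnrichmentRecord(rec.regulator, rec.cluster, rec.p_value, rec.odds_ratio, score)
        )
    return _rerank(out)


def rank_product_combine(
    rna_records: list[EnrichmentRecord], atac_records: list[EnrichmentRecord]
) -> pd.DataFrame:
    """Combine modality rankings by rank product sqrt(r_rna * r_atac).

    Regulators missing from one modality get that modality's worst rank
    plus one.  Output is sorted ascending by the combined statistic, ties
    broken by regulator name.
    """
    rna_rank = {r.regulator: r.rank for r in rna_records}
    atac_rank = {r.regulator: r.rank for r in atac_records}
    regulators = sorted(set(rna_rank) | set(atac_rank))
    worst_rna = max(rna_rank.values(), default=0) + 1
    worst_atac = max(atac_rank.values(), default=0) + 1
    rows = []
    for reg in regulators:
        rr = rna_rank.get(reg, worst_rna)
        ra = atac_rank.get(reg, worst_atac)
        rows.append((reg, rr, ra, math.sqrt(rr * ra)))
    df = pd.DataFrame(rows, columns=["regulator", "rank_rna", "rank_atac", "rank_product"])
    df = df.sort_values(["rank_product", "regulator"]).reset_index(drop=True)
    df["combined_rank"] = np.arange(1, len(df) + 1)
    return df


def filter_regulators(
    records: list[EnrichmentRecord],
    mean_expression: dict[str, float] | None = None,
    mean_rp: dict[str, float] | None = None,
    rank_by: str = "expression",
) -> list[EnrichmentRecord]:
    """Drop regulators with zero mean expression or mean RP < 0.5.

    Survivors are re-ranked by mean expression (RNA context) or mean RP
    (ATAC context).
    """
    kept = []
    for rec in records:
        if mean_expression is not None and mean_expression.get(rec.regulator, 0.0) == 0.0:
            continue
        if mean_rp is not None and mean_rp.get(rec.regulator, 0.0) < 0.5:
            continue
        kept.append(rec)
    if rank_by == "expression" and mean_expression is not None:
        keyfn = lambda r: (-mean_expression.get(r.regulator, 0.0), r.regulator)
    elif rank_by == "rp" and mean_rp is not None:
        keyfn = lambda r: (-mean_rp.get(r.regulator, 0.0), r.regulator)
    else:
        keyfn = lambda r: (-r.score, r.regulator)
    ordered = sorted(kept, key=keyfn)
    for rank, rec in enumerate(ordered, start=1):
        rec.rank = rank
    return ordered


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "regulator": [r.regulator for r in records],
            "cluster": [r.cluster for r in records],
            "p_value": [r.p_value for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "score": [r.score for r in records],
            "rank": [r.rank for r in records],
        }
    )
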