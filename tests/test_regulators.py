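import math

import numpy as np
import pytest
import scipy.stats

from scregpot.genome_io import GenomicInterval, PWM
from scregpot.regulators import (
    EnrichmentRecord,
    cluster_motifs,
    composite_score,
    filter_regulators,
    peakset_enrichment,
    propagate_family_scores,
    pwm_similarity,
    rank_product_combine,
)


def random_pwm(rng, name="M", length=8):
    return PWM(name, rng.dirichlet(np.ones(4) * 0.4, size=length))


def informative_pwm(name, seq):
    """Near-deterministic PWM for a nucleotide string (A=0..T=3)."""
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.full((len(seq), 4), 0.02)
    for i, base in enumerate(seq):
        probs[i, lookup[base]] = 0.94
    return PWM(name, probs)


def oracle_pwm_similarity(a, b, min_overlap=5):
    """Oracle: exhaustive offset evaluation with explicit column loops."""
    def ic(col):
        return 2 + sum(p * math.log2(p) for p in col if p > 0)

    def pcc(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    def directional(pa, pb):
        best = -np.inf
        la, lb = len(pa), len(pb)
        for offset in range(-(lb - min_overlap), la - min_overlap + 1):
            cols = [
                (pa[k], pb[k - offset])
                for k in range(max(0, offset), min(la, offset + lb))
            ]
            if len(cols) < min_overlap:
                continue
            num = sum(((ic(x) + ic(y)) / 2) * pcc(x, y) for x, y in cols)
            den = sum((ic(x) + ic(y)) / 2 for x, y in cols)
            if den > 0:
                best = max(best, num / den)
        return best

    rc = b.probs[::-1, ::-1]
    return min(1.0, max(directional(a.probs, b.probs), directional(a.probs, rc)))


class TestPWMSimilarity:
    def test_identical_pwms_score_one(self, rng):
        pwm = informative_pwm("X", "ACGTACGT")
        assert pwm_similarity(pwm, pwm) == pytest.approx(1.0)

    def test_reverse_complement_scores_one(self):
        pwm = informative_pwm("X", "AACGTG")
        assert pwm_similarity(pwm, pwm.reverse_complement()) == pytest.approx(1.0)

    def test_matches_exhaustive_offset_oracle(self, rng):
        a = informative_pwm("A", "ACGTAC")
        b = informative_pwm("B", "GTACGG")
        assert pwm_similarity(a, b) == pytest.approx(oracle_pwm_similarity(a, b))
        for _ in range(10):
            x, y = random_pwm(rng, "x", 7), random_pwm(rng, "y", 9)
            assert pwm_similarity(x, y) == pytest.approx(oracle_pwm_similarity(x, y))

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_pwm(rng, "a", 8), random_pwm(rng, "b", 8)
            assert pwm_similarity(a, b) == pytest.approx(pwm_similarity(b, a))

    def test_impossible_overlap_errors(self):
        short = PWM("s", np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            pwm_similarity(short, short, min_overlap=5)


class TestMotifClustering:
    def test_similar_pair_grouped_dissimilar_apart(self, rng):
        a = informative_pwm("A", "ACGTACGT")
        noisy = np.clip(a.probs + rng.normal(0, 0.005, a.probs.shape), 1e-3, None)
        b = PWM("B", noisy / noisy.sum(axis=1, keepdims=True))
        c = informative_pwm("C", "TTTTGGGG")
        assert pwm_similarity(a, b) > 0.7 > pwm_similarity(a, c)
        families = cluster_motifs([a, b, c], threshold=0.7)
        member_sets = {frozenset(f.members) for f in families}
        assert frozenset({"A", "B"}) in member_sets
        assert frozenset({"C"}) in member_sets

    def test_all_dissimilar_gives_singletons(self):
        pwms = [
            informative_pwm("A", "AAAACCCC"),
            informative_pwm("B", "GAGATCTG"),
            informative_pwm("C", "CGCGACAC"),
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert pwm_similarity(pwms[i], pwms[j]) < 0.7
        families = cluster_motifs(pwms, threshold=0.7)
        assert all(len(f.members) == 1 for f in families)

    def test_families_partition_the_regulator_set(self, rng):
        pwms = [random_pwm(rng, f"M{i}", 8) for i in range(6)]
        families = cluster_motifs(pwms)
        members = [m for f in families for m in f.members]
        assert sorted(members) == sorted(p.name for p in pwms)


def tile_universe(n, start=1000, width=500, gap=2000):
    return [
        GenomicInterval("chr1", start + i * (width + gap), start + i * (width + gap) + width)
        for i in range(n)
    ]


def hypergeom_tail_p(a, b, c, d):
    """Oracle: one-sided Fisher p as the hypergeometric upper tail."""
    N = a + b + c + d
    K = a + c       # peaks hit by the reference
    m = a + b       # cluster size
    return float(sum(scipy.stats.hypergeom.pmf(k, N, K, m) for k in range(a, min(K, m) + 1)))


class TestPeaksetEnrichment:
    def test_identical_reference_scores_highest(self, rng):
        universe = tile_universe(30)
        cluster = universe[:10]
        refs = {
            "planted": list(cluster),
            "decoy1": universe[10:20],
            "decoy2": [universe[i] for i in [0, 12, 17, 25, 28]],
        }
        records = peakset_enrichment(cluster, universe, refs)
        assert records[0].regulator == "planted" and records[0].rank == 1

    def test_p_matches_hypergeometric_oracle(self):
        universe = tile_universe(20)
        cluster = universe[:10]
        reference = universe[:8] + universe[10:12]  # a=8, b=2, c=2, d=8
        records = peakset_enrichment(cluster, universe, {"R": reference})
        (rec,) = records
        assert rec.p_value == pytest.approx(hypergeom_tail_p(8, 2, 2, 8), rel=1e-9)
        assert rec.odds_ratio == pytest.approx((8.5 * 8.5) / (2.5 * 2.5))

    def test_disjoint_reference_is_depleted(self):
        universe = tile_universe(20)
        records = peakset_enrichment(universe[:10], universe, {"R": universe[10:]})
        (rec,) = records
        assert rec.odds_ratio < 1
        assert rec.score < 0

    def test_random_universes_match_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 50))
            universe = tile_universe(n)
            cluster_idx = rng.choice(n, size=int(rng.integers(2, n // 2 + 2)), replace=False)
            ref_idx = rng.choice(n, size=int(rng.integers(2, n)), replace=False)
            cluster = [universe[i] for i in cluster_idx]
            reference = [universe[i] for i in ref_idx]
            (rec,) = peakset_enrichment(cluster, universe, {"R": reference})
            a = len(set(cluster_idx) & set(ref_idx))
            b = len(cluster_idx) - a
            c = len(ref_idx) - a
            d = n - a - b - c
            assert rec.p_value == pytest.approx(hypergeom_tail_p(a, b, c, d), rel=1e-9)

    def test_multiple_sets_keep_best(self):
        universe = tile_universe(20)
        cluster = universe[:10]
        refs = {"R": [list(cluster), universe[10:]]}  # strong and depleted set
        (rec,) = peakset_enrichment(cluster, universe, refs)
        assert rec.score > 0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty"):
            peakset_enrichment([], [], {"R": []})

    def test_cluster_peak_outside_universe_errors(self):
        universe = tile_universe(5)
        stray = GenomicInterval("chr9", 0, 100)
        with pytest.raises(ValueError, match="not in universe"):
            peakset_enrichment([stray], universe, {"R": universe[:2]})


class TestScoreCombination:
    def records(self, scores, cluster=0):
        recs = [
            EnrichmentRecord(name, cluster, 0.01, 2.0, s) for name, s in scores.items()
        ]
        for i, r in enumerate(sorted(recs, key=lambda r: -r.score), start=1):
            r.rank = i
        return recs

    def test_family_members_share_best_score(self):
        from scregpot.regulators import MotifFamily

        recs = self.records({"A": 5.0, "B": 1.0, "C": 3.0})
        fams = [MotifFamily(1, ["A", "B"]), MotifFamily(2, ["C"])]
        out = {r.regulator: r.score for r in propagate_family_scores(recs, fams)}
        assert out == {"A": 5.0, "B": 5.0, "C": 3.0}

    def test_propagation_idempotent_and_never_decreases(self):
        from scregpot.regulators import MotifFamily

        recs = self.records({"A": 5.0, "B": 1.0, "C": 3.0})
        fams = [MotifFamily(1, ["A", "B", "C"])]
        once = propagate_family_scores(recs, fams)
        twice = propagate_family_scores(once, fams)
        assert {r.regulator: r.score for r in once} == {r.regulator: r.score for r in twice}
        before = {r.regulator: r.score for r in recs}
        for r in once:
            assert r.score >= before[r.regulator]

    def test_rank_product_example(self):
        rna = self.records({"X": 9.0, "Y": 5.0, "Z": 1.0})     # ranks X=1,Y=2,Z=3
        atac = self.records({"X": 9.0, "Y": 1.0, "Z": 5.0})    # ranks X=1,Z=2,Y=3
        df = rank_product_combine(rna, atac).set_index("regulator")
        assert df.loc["X", "rank_product"] == pytest.approx(1.0)
        assert df.loc["X", "combined_rank"] == 1
        # (2,8) vs (3,3): sqrt(16)=4 loses to sqrt(9)=3
        assert math.sqrt(2 * 8) > math.sqrt(3 * 3)

    def test_rank_product_symmetric_in_modalities(self):
        rna = self.records({"X": 9.0, "Y": 5.0, "Z": 1.0})
        atac = self.records({"X": 1.0, "Y": 5.0, "Z": 9.0})
        a = rank_product_combine(rna, atac)[["regulator", "rank_product"]]
        b = rank_product_combine(atac, rna)[["regulator", "rank_product"]]
        assert a.equals(b)

    def test_missing_regulator_gets_worst_rank_plus_one(self):
        rna = self.records({"X": 9.0, "Y": 5.0})
        atac = self.records({"X": 9.0})
        df = rank_product_combine(rna, atac).set_index("regulator")
        assert df.loc["Y", "rank_atac"] == 2  # worst atac rank (1) + 1

    def test_filter_regulators(self):
        recs = self.records({"A": 5.0, "B": 4.0, "C": 3.0, "D": 2.0})
        expr = {"A": 2.0, "B": 0.0, "C": 1.0, "D": 3.0}
        rp = {"A": 0.6, "B": 0.9, "C": 0.4, "D": 2.0}
        out = filter_regulators(recs, expr, rp, rank_by="expression")
        names = [r.regulator for r in out]
        assert "B" not in names  # zero expression
        assert "C" not in names  # RP < 0.5
        assert names == ["D", "A"]  # re-ranked by mean expression


class TestCompositeScore:
    def test_sign_convention(self):
        assert composite_score(0.01, 4.0) == pytest.approx(2 * 2)
        assert composite_score(0.01, 0.25) < 0
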