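import itertools
import math

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

from scregpot.cluster_diff import (
    ClusterLabels,
    Embedding,
    cluster_cells,
    lsi_embed,
    normalize_log,
    normalize_peak_depth,
    pca_embed,
    select_variable_genes,
    wilcoxon_markers,
)
from scregpot.genome_io import NamedMatrix
from scregpot.integrate_eval import nmi


def named(values, prefix_r="g", prefix_c="c"):
    values = np.asarray(values, dtype=float)
    return NamedMatrix(
        values,
        [f"{prefix_r}{i}" for i in range(values.shape[0])],
        [f"{prefix_c}{j}" for j in range(values.shape[1])],
    )


class TestNormalization:
    def test_log_normalize_arithmetic(self):
        m = named([[10.0], [0.0]])
        out = normalize_log(m, scale=10_000).dense()
        assert out[0, 0] == pytest.approx(math.log(10_001))
        assert out[1, 0] == 0.0

    def test_all_zero_cell_stays_zero(self):
        out = normalize_log(named([[0.0, 5.0], [0.0, 5.0]])).dense()
        assert (out[:, 0] == 0).all()

    def test_delogged_columns_sum_to_scale(self, rng):
        m = named(rng.integers(0, 20, (30, 8)))
        out = normalize_log(m, scale=10_000).dense()
        sums = np.expm1(out).sum(axis=0)
        np.testing.assert_allclose(sums, 10_000, rtol=1e-8)

    def test_scale_equivariance(self, rng):
        counts = rng.integers(1, 10, (10, 4)).astype(float)
        doubled = counts.copy()
        doubled[:, 2] *= 7
        a = normalize_log(named(counts)).dense()
        b = normalize_log(named(doubled)).dense()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_peak_depth_weighting(self):
        m = named([[1.0], [1.0], [1.0], [1.0]], prefix_r="p")
        out = normalize_peak_depth(m).dense()
        np.testing.assert_allclose(out, 0.25)

    def test_peak_depth_columns_sum_to_one_or_zero(self, rng):
        m = named((rng.random((20, 6)) < 0.4).astype(float), prefix_r="p")
        m.values[:, 3] = 0
        sums = normalize_peak_depth(m).dense().sum(axis=0)
        for j, s in enumerate(sums):
            assert s == pytest.approx(0.0 if j == 3 else 1.0)

    def test_peak_depth_matches_loop_oracle(self, rng):
        m = named((rng.random((15, 5)) < 0.5).astype(float), prefix_r="p")
        out = normalize_peak_depth(m).dense()
        X = m.dense()
        for j in range(5):
            s = X[:, j].sum()
            for i in range(15):
                expected = X[i, j] / s if s else 0.0
                assert out[i, j] == pytest.approx(expected)

    def test_sparse_dense_agree(self, rng):
        X = rng.integers(0, 5, (12, 6)).astype(float)
        a = normalize_log(named(X)).dense()
        b = normalize_log(
            NamedMatrix(sp.csr_matrix(X), [f"g{i}" for i in range(12)], [f"c{j}" for j in range(6)])
        ).dense()
        np.testing.assert_allclose(a, b)


class TestVariableGenes:
    def test_constant_genes_never_selected(self, rng):
        X = rng.poisson(5.0, (50, 40)).astype(float)
        X[10] = 3.0  # constant gene
        m = named(X)
        assert "g10" not in select_variable_genes(m, n=50)

    def test_planted_overdispersed_recovered(self):
        rng = np.random.default_rng(7)
        n_genes, n_cells = 1000, 200
        mean = rng.uniform(1, 10, n_genes)
        X = rng.poisson(np.tile(mean, (n_cells, 1)).T).astype(float)
        planted = rng.choice(n_genes, 50, replace=False)
        for g in planted:
            lam = rng.gamma(0.5, mean[g] / 0.5, n_cells)  # strong overdispersion
            X[g] = rng.poisson(lam)
        m = named(X)
        top = set(select_variable_genes(m, n=50))
        recovered = sum(1 for g in planted if f"g{g}" in top)
        assert recovered >= 45

    def test_requesting_all_returns_permutation(self, rng):
        X = rng.poisson(5.0, (30, 50)).astype(float) + rng.random((30, 50))
        m = named(X)
        out = select_variable_genes(m, n=30)
        assert sorted(out) == sorted(m.row_names)

    def test_oversized_request_warns(self, rng):
        X = rng.poisson(5.0, (10, 20)).astype(float) + rng.random((10, 20))
        with pytest.warns(UserWarning, match="variable genes"):
            select_variable_genes(named(X), n=50)


class TestEmbeddings:
    def test_rank_one_matrix_single_dominant_component(self):
        col = (np.arange(30) % 3 == 0).astype(float)
        B = named(np.tile(col[:, None], (1, 12)), prefix_r="p")
        emb = lsi_embed(B, k=2, seed=0)
        # all cells identical -> all coordinates identical
        assert np.allclose(emb.coords, emb.coords[0], atol=1e-8)

    def test_two_disjoint_populations_separate(self, rng):
        n_peaks, n_cells = 100, 40
        B = np.zeros((n_peaks, n_cells))
        B[:50, :20] = rng.random((50, 20)) < 0.6
        B[50:, 20:] = rng.random((50, 20)) < 0.6
        emb = lsi_embed(named(B, prefix_r="p"), k=5, seed=0)
        # some component separates the groups linearly
        sep = False
        for k in range(5):
            a, b = emb.coords[:20, k], emb.coords[20:, k]
            if max(a.max(), b.max()) < min(a.min(), b.min()) or max(a.min(), b.min()) > min(a.max(), b.max()):
                sep = sep or (a.max() < b.min() or b.max() < a.min())
        assert any(
            emb.coords[:20, k].max() < emb.coords[20:, k].min()
            or emb.coords[20:, k].max() < emb.coords[:20, k].min()
            for k in range(5)
        )

    def test_k_too_large_errors(self, rng):
        B = named((rng.random((10, 8)) < 0.5).astype(float), prefix_r="p")
        with pytest.raises(ValueError):
            lsi_embed(B, k=8)
        with pytest.raises(ValueError):
            pca_embed(named(rng.random((10, 8))), k=10)

    def test_lsi_deterministic_under_seed(self, rng):
        B = named((rng.random((60, 30)) < 0.3).astype(float), prefix_r="p")
        a = lsi_embed(B, k=5, seed=11).coords
        b = lsi_embed(B, k=5, seed=11).coords
        np.testing.assert_array_equal(a, b)


class TestClustering:
    def two_blobs(self, n=200, d=5, gap=20.0, seed=0):
        # d matches the dimensionality regime the embeddings produce (>= 5)
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, d))
        b = rng.normal(0, 1, (n, d))
        b[:, 0] += gap
        coords = np.vstack([a, b])
        names = [f"c{i}" for i in range(2 * n)]
        return Embedding(coords, names, method="pca"), [0] * n + [1] * n

    def test_two_blobs_perfectly_recovered(self):
        emb, truth = self.two_blobs()
        labels = cluster_cells(emb, n_neighbors=20, resolution=0.6, seed=2020)
        pred = [labels.labels[c] for c in emb.cell_names]
        assert len(set(pred)) == 2
        assert nmi(truth, pred) == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        emb, _ = self.two_blobs()
        l1 = cluster_cells(emb, seed=2020)
        l2 = cluster_cells(emb, seed=2020)
        assert l1.labels == l2.labels

    def test_duplicating_a_blob_keeps_partition_structure(self):
        emb, truth = self.two_blobs(n=100)
        # append a jittered copy of the first blob
        extra = emb.coords[:100] + 1e-6
        coords = np.vstack([emb.coords, extra])
        names = emb.cell_names + [f"dup{i}" for i in range(100)]
        labels = cluster_cells(Embedding(coords, names, "pca"), seed=2020)
        pred = [labels.labels[c] for c in names]
        # each duplicate lands with its original, and blob clusters never mix
        for i in range(100):
            assert pred[200 + i] == pred[i]
        assert not ({pred[i] for i in range(100)} & {pred[i] for i in range(100, 200)})

    def test_too_few_cells_errors(self):
        emb = Embedding(np.zeros((5, 2)), [f"c{i}" for i in range(5)])
        with pytest.raises(ValueError):
            cluster_cells(emb, n_neighbors=20)


def exact_ranksum_p(x, y):
    """Oracle: exact two-sided rank-sum p by enumerating all group splits."""
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(combined) + 1) / 2
    count = total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        w = ranks[list(subset)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxonMarkers:
    def open_thresholds(self):
        return {"min_logfc": -100.0, "min_pct": 0.0, "max_p": 1.1}

    def test_identical_distributions_yield_no_markers(self, rng):
        X = rng.poisson(5.0, (20, 40)).astype(float)
        labels = ClusterLabels.from_arrays([f"c{j}" for j in range(40)], [0] * 20 + [1] * 20)
        records = wilcoxon_markers(named(np.log1p(X)), labels)
        assert records == []

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3], [10, 11, 12]),
            ([1, 5, 2, 8], [3, 9, 4, 7]),
            ([1, 1, 2, 3, 3], [2, 4, 4, 5, 6, 7]),
            ([0, 0, 1, 2, 5, 6, 7, 9], [1, 3, 3, 4, 8, 8, 10, 11]),
        ],
    )
    def test_p_matches_exact_enumeration_oracle(self, x, y):
        x, y = np.array(x, float), np.array(y, float)
        X = np.concatenate([x, y])[None, :]
        labels = ClusterLabels.from_arrays(
            [f"c{j}" for j in range(len(x) + len(y))],
            [0] * len(x) + [1] * len(y),
        )
        records = wilcoxon_markers(named(X), labels, self.open_thresholds())
        got = {r.cluster: r.p_value for r in records if r.feature == "g0"}
        exact = exact_ranksum_p(x, y)
        for p in got.values():
            assert abs(p - exact) <= 0.02

    def test_logfc_threshold_excludes_weak_genes(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(20.0, 60).astype(float)
        weak = np.log1p(np.concatenate([base[:30] * 1.2, base[30:]]))  # logFC ~ 0.18
        strong = np.log1p(np.concatenate([base[:30] * 3.0, base[30:]]))
        X = np.vstack([weak, strong])
        labels = ClusterLabels.from_arrays([f"c{j}" for j in range(60)], [0] * 30 + [1] * 30)
        records = wilcoxon_markers(named(X), labels)
        feats = {(r.feature, r.cluster) for r in records}
        assert ("g1", 0) in feats
        assert ("g0", 0) not in feats

    def test_small_cluster_skipped_with_warning(self, rng):
        X = rng.poisson(5.0, (5, 10)).astype(float)
        labels = ClusterLabels.from_arrays(
            [f"c{j}" for j in range(10)], [0] * 8 + [1] * 2
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            wilcoxon_markers(named(X), labels, self.open_thresholds())
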