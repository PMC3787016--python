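"""Projection features (RMS cluster amplitudes), codebooks, and assignment."""

import numpy as np
import pytest

from nsstruct import codebook as cb
from nsstruct import ic_basis


def _unit_filters(l, idxs, scale=0):
    out = []
    for i in idxs:
        w = np.zeros(l)
        w[i] = 1.0
        out.append(ic_basis.ICFilter(weights=w, scale_index=scale, diameter=None))
    return out


class TestProjectPatch:
    def test_worked_rms_example(self):
        """Cluster {e1, e2}, P.e1 = 3, P.e2 = 4 -> sqrt((9+16)/2)."""
        cluster = _unit_filters(5, [0, 1])
        P = np.array([3.0, 4.0, 0.0, 0.0, 0.0])
        a = cb.project_patch(P, cluster)
        assert np.isclose(a, np.sqrt(12.5))

    def test_zero_patch_zero_feature(self):
        cluster = _unit_filters(5, [0, 1, 2])
        assert cb.project_patch(np.zeros(5), cluster) == 0.0

    def test_absolute_homogeneity(self):
        rng = np.random.default_rng(0)
        cluster = [
            ic_basis.ICFilter(weights=rng.standard_normal(8), scale_index=0,
                              diameter=None)
            for _ in range(3)
        ]
        P = rng.standard_normal(8)
        a = cb.project_patch(P, cluster)
        for c in (-2.5, 0.0, 3.0):
            assert np.isclose(cb.project_patch(c * P, cluster), abs(c) * a)

    def test_cluster_without_matching_scale_yields_zero(self):
        cluster = _unit_filters(5, [0], scale=1)
        P = np.ones(5)
        assert cb.project_patch(P, cluster) == 0.0  # P has scale_index 0

    def test_nonnegativity(self):
        rng = np.random.default_rng(1)
        cluster = [
            ic_basis.ICFilter(weights=rng.standard_normal(6), scale_index=0,
                              diameter=None)
            for _ in range(4)
        ]
        for _ in range(20):
            assert cb.project_patch(rng.standard_normal(6), cluster) >= 0


def _toy_cluster_set(l=6, n_clusters=3):
    clusters = []
    for i in range(n_clusters):
        clusters.append(_unit_filters(l, [i, (i + 1) % l]))
    return ic_basis.ICClusterSet(
        clusters=clusters, n_orientation_bins=16, centroids=np.zeros((n_clusters, 6))
    )


class TestHexFeatures:
    def test_dimensionality_is_7N(self):
        cs = _toy_cluster_set(n_clusters=3)
        patches = np.random.default_rng(0).random((5, 7, 6))
        F = cb.batch_hex_features(patches, cs, 0, center_patches=False)
        assert F.shape == (5, 21)
        # with 100 clusters the vector has length 700
        cs100 = _toy_cluster_set(l=150, n_clusters=100)
        F100 = cb.batch_hex_features(
            np.random.default_rng(1).random((2, 7, 150)), cs100, 0,
            center_patches=False,
        )
        assert F100.shape[1] == 700

    def test_matches_object_level_projection(self):
        from nsstruct.sampling import CircularPatch

        cs = _toy_cluster_set(n_clusters=3)
        rng = np.random.default_rng(2)
        arr = rng.random((1, 7, 6))
        F = cb.batch_hex_features(arr, cs, 0, center_patches=False)
        patches = [
            CircularPatch(values=arr[0, k], scale_index=0, diameter=None)
            for k in range(7)
        ]
        hv = cb.hex_features(patches, cs)
        assert np.allclose(hv.values, F[0])

    def test_zero_patches_zero_vector(self):
        cs = _toy_cluster_set()
        F = cb.batch_hex_features(np.zeros((3, 7, 6)), cs, 0, center_patches=False)
        assert np.allclose(F, 0)

    def test_block_order_matters(self):
        cs = _toy_cluster_set()
        rng = np.random.default_rng(3)
        arr = rng.random((1, 7, 6))
        F1 = cb.batch_hex_features(arr, cs, 0, center_patches=False)
        F2 = cb.batch_hex_features(arr[:, ::-1], cs, 0, center_patches=False)
        assert not np.allclose(F1, F2)


class TestCodebook:
    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(0)
        means = rng.uniform(0, 50, size=(4, 14))
        X = np.abs(np.vstack([m + 0.1 * rng.standard_normal((50, 14)) for m in means]))
        book = cb.build_category_codebook(X, 4, seed=0, category="a")
        d = np.linalg.norm(book.centroids[:, None] - means[None], axis=-1)
        assert d.min(axis=0).max() < 0.5  # every blob mean recovered

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(1).random((200, 10))
        b1 = cb.build_category_codebook(X, 5, seed=7)
        b2 = cb.build_category_codebook(X, 5, seed=7)
        assert np.array_equal(b1.centroids, b2.centroids)

    def test_K_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            cb.build_category_codebook(np.random.default_rng(2).random((5, 4)), 6, 0)

    def test_pooling_preserves_sizes_and_provenance(self):
        rng = np.random.default_rng(3)
        books = [
            cb.build_category_codebook(rng.random((60, 8)), 5, seed=i, category=c)
            for i, c in enumerate("abc")
        ]
        master = cb.NSSCodebook.pool(books)
        assert master.size == sum(b.size for b in books)
        assert list(np.unique(master.source_category)) == ["a", "b", "c"]


class TestAssign:
    def test_exact_centroid_maps_to_itself(self):
        book = cb.NSSCodebook(
            centroids=np.eye(4), source_category=np.array(list("aaaa"))
        )
        assert cb.assign_nss(np.eye(4)[2], book) == 2

    def test_tie_breaks_to_lowest_index(self):
        cents = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        book = cb.NSSCodebook(
            centroids=cents, source_category=np.array(list("aaaa"))
        )
        # (1, 0) is equidistant from centroids 0, 1, 3
        assert cb.assign_nss(np.array([1.0, 0.0]), book) == 0

    def test_agrees_with_brute_force_search(self):
        rng = np.random.default_rng(4)
        cents = rng.random((30, 12))
        book = cb.NSSCodebook(
            centroids=cents, source_category=np.array(["x"] * 30)
        )
        X = rng.random((1000, 12))
        got = cb.assign_nss(X, book)
        expected = np.array(
            [np.argmin(((x - cents) ** 2).sum(axis=1)) for x in X]
        )
        assert np.array_equal(got, expected)


class TestSelect:
    def _book(self, k=3):
        return cb.NSSCodebook(
            centroids=np.eye(k), source_category=np.array(["a"] * k)
        )

    def test_occurrence_count_thresholding(self):
        """Max per-category image counts (9, 7, 2) with M_c = 7 keep one NSS."""
        book = self._book(3)
        assignments = []
        for i in range(9):
            assignments.append((f"a{i}", "cat_a", [0] + ([1] if i < 7 else [])))
        assignments.append(("b0", "cat_b", [2]))
        assignments.append(("b1", "cat_b", [2]))
        sel = cb.select_nss(book, assignments, M_c=7)
        assert sel.selected.tolist() == [True, False, False]

    def test_zero_threshold_keeps_everything_occurring(self):
        book = self._book(3)
        sel = cb.select_nss(book, [("i", "a", [0, 2])], M_c=0)
        assert sel.selected.tolist() == [True, False, True]

    def test_boundary_is_strict(self):
        book = self._book(1)
        assignments = [(f"i{i}", c, [0]) for c in "ab" for i in range(7)]
        sel = cb.select_nss(book, assignments, M_c=7)
        assert not sel.selected[0]  # exactly M_c in every category -> dropped


class TestVariationPCA:
    def test_identical_members(self):
        members = np.tile(np.random.default_rng(0).random(10), (5, 1))
        _, cum = cb.nss_variation_pca(members)
        assert np.isclose(cum[0], 1.0)

    def test_isotropic_cloud_flat_spectrum(self):
        X = np.random.default_rng(1).standard_normal((4000, 6))
        _, cum = cb.nss_variation_pca(X, n_components=6)
        ratios = np.diff(np.concatenate([[0], cum]))
        assert ratios.max() / ratios.min() < 1.3

    def test_clustered_members_dominate_unclustered_pool(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(-3, 3, (3, 20))
        clustered = np.vstack(
            [c + 0.1 * rng.standard_normal((34, 20)) for c in centers]
        )
        pool = rng.uniform(-3, 3, (102, 20))
        _, cum_c = cb.nss_variation_pca(clustered, n_components=10)
        _, cum_p = cb.nss_variation_pca(pool, n_components=10)
        # a quantized (clustered) set concentrates variance in fewer PCs
        assert np.all(cum_c[:5] >= cum_p[:5])
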