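"""Grid occurrence maps, adjacency matrices, spectra, Fisher and occurrence stats."""

import numpy as np
import pandas as pd
import pytest

from nsstruct import spatial


def brute_force_adjacency(counts, L_c, metric="manhattan"):
    """Independent all-pairs double loop over the 64x64 cell pairs."""
    A = np.zeros((64, 64))
    flat = counts.ravel()
    for n in range(64):
        for m in range(64):
            if n == m:
                continue
            nr, nc = divmod(n, 8)
            mr, mc = divmod(m, 8)
            L = spatial.grid_distance((nr, nc), (mr, mc), metric)
            if flat[n] > 0 and flat[m] > 0 and L < L_c:
                A[n, m] = min(flat[n], flat[m])
    return A


class TestGridOccurrence:
    def test_center_of_image_hits_center_cell(self):
        m = spatial.grid_occurrence([((400, 400), 5)], (800, 800), 5)
        assert m.counts[4, 4] == 1 and m.counts.sum() == 1

    def test_empty_and_conservation(self):
        empty = spatial.grid_occurrence([], (100, 100), 0)
        assert empty.counts.sum() == 0
        rng = np.random.default_rng(0)
        pts = [((int(r), int(c)), 1) for r, c in rng.integers(0, 100, (10, 2))]
        m = spatial.grid_occurrence(pts, (100, 100), 1)
        assert m.counts.sum() == 10


class TestGridDistance:
    def test_worked_cases(self):
        assert spatial.grid_distance((0, 0), (0, 0)) == 0
        assert spatial.grid_distance((1, 2), (3, 5)) == 5  # 2 + 3
        assert spatial.grid_distance((1, 2), (3, 5), "chebyshev") == 3

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n, m = [tuple(x) for x in rng.integers(0, 8, (2, 2))]
            assert spatial.grid_distance(n, m) == spatial.grid_distance(m, n)


class TestBuildAdjacency:
    def test_single_cell_zero_matrix_zero_spectrum(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[3, 3] = 7
        A = spatial.build_adjacency(counts, L_c=3)
        assert not A.entries.any()
        assert np.allclose(spatial.spectral_feature(A, 3), 0)

    def test_two_cell_min_count_and_pm_spectrum(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[2, 2], counts[2, 4] = 3, 5  # L = 2 < L_c = 3
        A = spatial.build_adjacency(counts, L_c=3)
        n, m = 2 * 8 + 2, 2 * 8 + 4
        assert A.entries[n, m] == 3 and A.entries[m, n] == 3
        lam = spatial.spectral_feature(A, 3)
        assert np.allclose(sorted(lam), [-3, 0, 3])
        # magnitude tie breaks to the positive eigenvalue
        assert spatial.spectral_feature(A, 1)[0] == 3

    def test_threshold_excludes_far_cells(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 0], counts[2, 2] = 2, 2  # L = 4
        A = spatial.build_adjacency(counts, L_c=3)
        assert not A.entries.any()

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            counts = rng.integers(0, 4, (8, 8)) * (rng.random((8, 8)) < 0.3)
            L_c = int(rng.integers(1, 6))
            A = spatial.build_adjacency(counts, L_c)
            assert np.array_equal(A.entries, brute_force_adjacency(counts, L_c))

    def test_structure_contract(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 5, (8, 8))
        A = spatial.build_adjacency(counts, L_c=4).entries
        assert A.shape == (64, 64)
        assert np.array_equal(A, A.T)
        assert np.trace(A) == 0

    def test_monotone_in_L_c(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 3, (8, 8))
        prev = spatial.build_adjacency(counts, 1).entries
        for L_c in range(2, 8):
            cur = spatial.build_adjacency(counts, L_c).entries
            assert np.all(cur[prev > 0] == prev[prev > 0])  # nothing removed
            prev = cur


class TestSpectralFeature:
    def test_eigenvalue_sum_is_trace_zero(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 4, (8, 8))
        A = spatial.build_adjacency(counts, 3)
        lam = spatial.spectral_feature(A, 64)
        assert abs(lam.sum()) < 1e-8

    def test_asymmetric_input_rejected(self):
        M = np.zeros((64, 64))
        M[0, 1] = 1.0
        with pytest.raises(ValueError):
            spatial.spectral_feature(M, 3)

    def test_fast_path_matches_full_eigendecomposition(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            counts = rng.integers(0, 4, (8, 8)) * (rng.random((8, 8)) < 0.4)
            A = spatial.build_adjacency(counts, 3)
            assert np.allclose(
                spatial.spectral_feature(A, 5),
                spatial.adjacency_spectrum(counts, 3, 5),
            )

    def test_dispersed_occurrences_spread_spectrum(self):
        """Same total count: near-dispersed cells beat one concentrated cell."""
        lone = np.zeros((8, 8), dtype=int)
        lone[4, 4] = 9
        spread = np.zeros((8, 8), dtype=int)
        spread[3:6, 3:6] = 1
        lam_lone = spatial.adjacency_spectrum(lone, 3, 1)
        lam_spread = spatial.adjacency_spectrum(spread, 3, 1)
        assert abs(lam_spread[0]) > abs(lam_lone[0])


class TestFisherMatrix:
    def test_identical_distributions_score_zero(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((200, 3))
        F = spatial.fisher_matrix({"a": X, "b": X.copy()}, top_d=3)
        assert F.loc["a", "b"] < 1e-12

    def test_closed_form_unit_gaussians(self):
        """N(0,1) vs N(2,1) in 1-D has Fisher score 4 / (1+1) = 2."""
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, (200_0, 1))
        b = rng.normal(2, 1, (200_0, 1))
        F = spatial.fisher_matrix({"a": a, "b": b}, top_d=1)
        assert np.isclose(F.loc["a", "b"], 2.0, rtol=0.1)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal((30, 2)), 1 + rng.standard_normal((30, 2))
        F1 = spatial.fisher_matrix({"a": a, "b": b})
        F2 = spatial.fisher_matrix({"b": b, "a": a})
        assert np.isclose(F1.loc["a", "b"], F2.loc["a", "b"])
        assert F1.loc["a", "a"] == 0

    def test_missing_category_warns_with_zero_row(self):
        with pytest.warns(UserWarning):
            F = spatial.fisher_matrix(
                {"a": np.random.default_rng(0).standard_normal((5, 2)),
                 "b": np.empty((0, 2))}
            )
        assert (F.loc["b"] == 0).all()


class TestOccurrenceMatrix:
    def test_category_exclusive_nss_gives_identity(self):
        cats = {f"i{k}": "ab"[k % 2] for k in range(10)}
        srcs = {img: {cat} for img, cat in cats.items()}
        M = spatial.occurrence_matrix(cats, srcs)
        assert np.allclose(M.values, np.eye(2))

    def test_toy_row_normalization(self):
        """Counts [[10, 4], [2, 8]] normalize to [[1, .4], [.25, 1]]."""
        cats, srcs = {}, {}
        # 10 images of category a, 8 of b
        for k in range(10):
            img = f"a{k}"
            cats[img] = "a"
            srcs[img] = {"a", "b"} if k < 2 else {"a"}
        for k in range(8):
            img = f"b{k}"
            cats[img] = "b"
            srcs[img] = {"a", "b"} if k < 4 else {"b"}
        M = spatial.occurrence_matrix(cats, srcs, categories=["a", "b"])
        assert np.allclose(M.values, [[1.0, 0.4], [0.25, 1.0]])

    def test_diagonal_is_one_and_entries_nonnegative(self):
        rng = np.random.default_rng(10)
        cats = {f"i{k}": "abc"[k % 3] for k in range(30)}
        srcs = {
            img: set(rng.choice(list("abc"), rng.integers(1, 4), replace=False))
            | {cat}
            for img, cat in cats.items()
        }
        M = spatial.occurrence_matrix(cats, srcs)
        assert np.allclose(np.diag(M.values), 1.0)
        assert (M.values >= 0).all()
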