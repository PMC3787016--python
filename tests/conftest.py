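"""Shared fixtures.

The expensive end-to-end runs (full synthetic benchmark and the two
single-channel contrast sets) are computed once per session and shared by
the pipeline tests and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from nsstruct import NSSModel, get_profile
from nsstruct import ic_basis, sampling
from nsstruct.synthetic import make_benchmark, make_contrast_set

SEED = 1


@pytest.fixture(scope="session")
def tiny_profile():
    """Desk-scale profile shrunk further for fast unit tests."""
    return get_profile(
        "synthetic",
        step=12,
        n_ics=12,
        ica_patches=4000,
        n_ic_clusters=8,
        nss_per_category=12,
        codebook_samples=4000,
        occurrence_threshold=1,
        kmeans_restarts=2,
    )


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small 2-category image set for fast structural tests."""
    return make_benchmark(n_categories=2, n_per_category=8, seed=SEED, size=(160, 160))


@pytest.fixture(scope="session")
def benchmark_fit():
    """Full 3x40 synthetic benchmark fitted with the desk-scale profile."""
    bench = make_benchmark(n_per_category=40, seed=SEED)
    model = NSSModel(
        bench.images, bench.labels, get_profile("synthetic"),
        train_mask=bench.is_train,
    )
    return bench, model.fit(seed=SEED)


@pytest.fixture(scope="session")
def satellite_contrast():
    """(hexagon accuracy, single-circle accuracy) on blend-direction data."""
    bench = make_contrast_set("satellite", n_per_category=24, seed=SEED)
    prof = get_profile("synthetic")
    model = NSSModel(bench.images, bench.labels, prof, train_mask=bench.is_train)
    acc_hex = model.fit(seed=SEED).accuracy
    acc_circle = model.fit(seed=SEED, profile=prof.replace(hexagon=False)).accuracy
    return acc_hex, acc_circle


@pytest.fixture(scope="session")
def layout_contrast():
    """(with-adjacency, without-adjacency) accuracy on layout-only data."""
    bench = make_contrast_set("layout", n_per_category=24, seed=SEED)
    prof = get_profile("synthetic", distance_metric="chebyshev", L_c=3)
    model = NSSModel(bench.images, bench.labels, prof, train_mask=bench.is_train)
    acc_with = model.fit(seed=SEED).accuracy
    acc_without = model.fit(seed=SEED, profile=prof.replace(use_adjacency=False)).accuracy
    return acc_with, acc_without


def synthetic_gabor_bank(n: int = 50, diameter: int = 16, seed: int = SEED):
    """Known-parameter Gabor filters spanning 16 orientations."""
    rng = np.random.default_rng(seed)
    mask = sampling.build_circular_mask(diameter)
    bank = []
    for i in range(n):
        theta = (i % 16 + 0.5) * np.pi / 16
        p = ic_basis.GaborParams(
            amp=1.0,
            x0=diameter / 2 + rng.uniform(-1, 1),
            y0=diameter / 2 + rng.uniform(-1, 1),
            sx=rng.uniform(2.2, 3.0),
            sy=rng.uniform(4.0, 5.5),
            theta=theta,
            freq=rng.uniform(0.12, 0.2),
            phi=rng.uniform(0, 2 * np.pi),
        )
        img = ic_basis.render_gabor(p, diameter)
        bank.append((p, img[mask.grid_mask()]))
    return bank


@pytest.fixture(scope="session")
def gabor_bank():
    return synthetic_gabor_bank()


def ica_recovery_amari(seed: int = SEED, n_sources: int = 8, n_patches: int = 20_000):
    """Amari index of FastICA recovery on a sparse linear-mixture model."""
    rng = np.random.default_rng(seed)
    l = 64
    A = rng.standard_normal((l, n_sources))
    S = rng.laplace(size=(n_patches, n_sources))
    X = S @ A.T
    filters = ic_basis.learn_ica(X, n_sources, seed=seed)
    W = np.array([f.weights for f in filters])
    return amari_index(W @ A)


def amari_index(P: np.ndarray) -> float:
    P = np.abs(P)
    m = P.shape[0]
    r = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    c = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((r.sum() + c.sum()) / (2 * m * (m - 1)))
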