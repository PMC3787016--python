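"""Projection features, hexagonal feature vectors, and NSS codebooks.

The feature of a patch P for IC cluster i is the root-mean-square amplitude
of the cluster's same-scale filters: a_i = sqrt( (1/m) * sum_j (P . A_j)^2 ).
Concatenating the N-dim feature vectors of the 7 hexagon patches gives a
7N-dim sample; per-category K-means over such samples yields the NSS
codebook, and the pooled per-category books form the master book.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from .ic_basis import ICClusterSet, ICFilter
from .sampling import CircularPatch

__all__ = [
    "HexFeatureVector",
    "NSSCodebook",
    "project_patch",
    "hex_features",
    "batch_hex_features",
    "build_category_codebook",
    "assign_nss",
    "select_nss",
    "nss_variation_pca",
]


@dataclass
class HexFeatureVector:
    """7xN nonnegative features of one hexagonal sample at one scale.

    Patch-major layout: block 0 is the centre patch, blocks 1..6 the
    satellites counterclockwise from the +col axis.  The order is part of
    the code — permuting blocks changes the vector.
    """

    values: np.ndarray  # length 7*N
    scale_index: int
    location: tuple[int, int] = (0, 0)
    image_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("hex features must be nonnegative")


def project_patch(patch, cluster: Sequence[ICFilter]) -> float:
    """RMS amplitude of a patch over the same-scale filters of one IC cluster.

    Only filters whose ``scale_index`` matches the patch contribute; a
    cluster with no filter at the patch's scale yields 0.  The feature is
    nonnegative and absolutely homogeneous: project_patch(c*P) = |c| * a.
    """
    if isinstance(patch, CircularPatch):
        values, scale = patch.values, patch.scale_index
    else:
        values, scale = np.asarray(patch, dtype=float), 0
    W = [f.weights for f in cluster if f.scale_index == scale]
    if not W:
        return 0.0
    amps = np.array(W) @ values
    return float(np.sqrt(np.mean(amps**2)))


def hex_features(
    hex_patches: Sequence[CircularPatch], clusters: ICClusterSet
) -> HexFeatureVector:
    """Concatenate the per-cluster features of the 7 hexagon patches."""
    if len(hex_patches) != 7:
        raise ValueError(f"expected 7 patches, got {len(hex_patches)}")
    scale = hex_patches[0].scale_index
    blocks = [
        [project_patch(p, cl) for cl in clusters.clusters] for p in hex_patches
    ]
    return HexFeatureVector(
        values=np.concatenate(blocks),
        scale_index=scale,
        location=hex_patches[0].source[1],
        image_id=hex_patches[0].source[0],
    )


def batch_hex_features(
    patch_matrix: np.ndarray,
    clusters: ICClusterSet,
    scale_index: int,
    center_patches: bool = True,
) -> np.ndarray:
    """Vectorized hex features: (n, 7, l) patches -> (n, 7N) features.

    Per-patch mean subtraction (the pre-normalization used before ICA) is
    applied unless disabled.
    """
    n = patch_matrix.shape[0]
    N = clusters.n_clusters
    if n == 0:
        return np.empty((0, 7 * N))
    flat = patch_matrix.reshape(n * 7, -1)
    if center_patches:
        flat = flat - flat.mean(axis=1, keepdims=True)
    W, cidx = clusters.filters_matrix(scale_index)
    out = np.zeros((n * 7, N))
    if W.size:
        amps = flat @ W.T  # (7n, m_total)
        counts = np.bincount(cidx, minlength=N).astype(float)
        sq = np.zeros((n * 7, N))
        np.add.at(sq.T, cidx, (amps**2).T)
        nonzero = counts > 0
        out[:, nonzero] = np.sqrt(sq[:, nonzero] / counts[nonzero])
    return out.reshape(n, 7 * N)


@dataclass
class NSSCodebook:
    """K-means centroids in 7N space with per-centroid category provenance."""

    centroids: np.ndarray  # (K, 7N)
    source_category: np.ndarray  # (K,) labels
    occurrence_threshold: int = 0  # M_c used by the last selection
    selected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.source_category = np.asarray(self.source_category)
        if self.selected is None:
            self.selected = np.ones(len(self.centroids), dtype=bool)

    @property
    def size(self) -> int:
        return len(self.centroids)

    @classmethod
    def pool(cls, books: Sequence["NSSCodebook"]) -> "NSSCodebook":
        """Master book: concatenation of the per-category books."""
        return cls(
            centroids=np.vstack([b.centroids for b in books]),
            source_category=np.concatenate([b.source_category for b in books]),
        )


def build_category_codebook(
    features, K: int, seed: int, category="", restarts: int = 10
) -> NSSCodebook:
    """K-means codebook over one category's hex feature vectors.

    Samples are (location, scale) feature vectors pooled over all scales.
    Duplicate centroids are dropped, so the book may hold fewer than K
    entries.  Deterministic given ``seed``.
    """
    if isinstance(features, (list, tuple)) and features and isinstance(
        features[0], HexFeatureVector
    ):
        X = np.array([f.values for f in features])
    else:
        X = np.asarray(features, dtype=float)
    if K > len(X):
        raise ValueError(f"K={K} exceeds sample count {len(X)}")
    km = KMeans(
        n_clusters=K, init="k-means++", n_init=restarts,
        max_iter=300, tol=1e-4, random_state=seed % (2**31),
    )
    km.fit(X)
    cents = km.cluster_centers_
    _, unique_idx = np.unique(np.round(cents, 12), axis=0, return_index=True)
    cents = cents[np.sort(unique_idx)]
    return NSSCodebook(
        centroids=cents,
        source_category=np.array([category] * len(cents)),
    )


def assign_nss(feature, book: NSSCodebook, chunk: int = 4096) -> np.ndarray:
    """Nearest-centroid (Euclidean) NSS index; ties break to the lowest index.

    Accepts one HexFeatureVector / vector or an (n, 7N) matrix; returns an
    int array (scalar array for a single vector).
    """
    if book.size == 0:
        raise ValueError("empty codebook")
    if isinstance(feature, HexFeatureVector):
        X = feature.values[None, :]
    else:
        X = np.atleast_2d(np.asarray(feature, dtype=float))
    out = np.empty(len(X), dtype=int)
    for s in range(0, len(X), chunk):
        block = X[s : s + chunk]
        # squared distances; argmin picks the lowest index on ties
        d2 = (
            (block**2).sum(axis=1)[:, None]
            - 2 * block @ book.centroids.T
            + (book.centroids**2).sum(axis=1)[None, :]
        )
        out[s : s + chunk] = np.argmin(d2, axis=1)
    return out if out.size > 1 else out[0]


def select_nss(
    book: NSSCodebook,
    image_assignments: Iterable[tuple[str, object, Iterable[int]]],
    M_c: int,
) -> NSSCodebook:
    """Keep NSSs occurring in more than ``M_c`` images of at least one category.

    ``image_assignments`` yields (image_id, category, nss_ids present in the
    image); occurrence in an image means at least one (location, scale)
    assignment.  Selection only flips the ``selected`` mask; centroid
    identities and order are untouched.
    """
    image_assignments = list(image_assignments)
    cats = list(dict.fromkeys(cat for _, cat, _ in image_assignments))
    cat_pos = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((book.size, len(cats)), dtype=int)
    for _img, cat, nss_ids in image_assignments:
        present = np.unique(np.asarray(list(nss_ids), dtype=int))
        counts[present, cat_pos[cat]] += 1
    selected = (counts > M_c).any(axis=1) if len(cats) else np.zeros(book.size, bool)
    return NSSCodebook(
        centroids=book.centroids,
        source_category=book.source_category,
        occurrence_threshold=M_c,
        selected=selected,
    )


def nss_variation_pca(members: np.ndarray, n_components: int | None = None):
    """PCA over the pixel concatenations of one NSS's member samples.

    Returns ``(components, cumulative_explained_variance_ratio)``; used to
    compare the variability of an NSS against a matched random-patch pool.
    Fewer members than requested components truncates; identical members
    yield a first component explaining everything.
    """
    X = np.asarray(members, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 member samples")
    max_nc = min(len(X) - 1, X.shape[1])
    if n_components is None or n_components > max_nc:
        n_components = max_nc
    if np.allclose(X.std(axis=0), 0):
        comps = np.zeros((n_components, X.shape[1]))
        ratio = np.zeros(n_components)
        ratio[0] = 1.0
        return comps, np.cumsum(ratio)
    pca = PCA(n_components=n_components)
    pca.fit(X)
    return pca.components_, np.cumsum(pca.explained_variance_ratio_)
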