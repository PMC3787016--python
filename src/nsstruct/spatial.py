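"""Graph-spectral encoding of where an NSS occurs within an image.

Each image is partitioned into an 8x8 grid; the occurrences of one NSS
define a 64x64 symmetric occurrence-adjacency matrix connecting grid cells
closer than a threshold L_c, weighted by the smaller of the two cell counts.
The N_c largest-magnitude eigenvalues of that matrix summarize how dispersed
the NSS is; dispersed arrangements spread the spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRID",
    "GridOccurrenceMap",
    "AdjacencyMatrix",
    "grid_occurrence",
    "grid_distance",
    "build_adjacency",
    "spectral_feature",
    "adjacency_spectrum",
    "fisher_matrix",
    "occurrence_matrix",
]

GRID = 8  # cells per image side


@dataclass
class GridOccurrenceMap:
    """8x8 occurrence counts of one NSS in one image."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (GRID, GRID):
            raise ValueError(f"expected {GRID}x{GRID} counts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class AdjacencyMatrix:
    """64x64 symmetric occurrence-adjacency matrix with zero diagonal."""

    entries: np.ndarray
    L_c: int

    def __post_init__(self):
        self.entries = np.asarray(self.entries)
        if self.entries.shape != (GRID * GRID, GRID * GRID):
            raise ValueError("adjacency matrix must be 64x64")


def grid_occurrence(
    assignments: Iterable[tuple[tuple[int, int], int]],
    image_shape: tuple[int, int],
    nss_id: int,
) -> GridOccurrenceMap:
    """Tally the (location, nss_id) assignments of one NSS onto the 8x8 grid.

    A location (row, col) falls in cell (floor(row*8/H), floor(col*8/W)).
    """
    h, w = image_shape[:2]
    counts = np.zeros((GRID, GRID), dtype=int)
    for (row, col), nid in assignments:
        if nid != nss_id:
            continue
        counts[min(row * GRID // h, GRID - 1), min(col * GRID // w, GRID - 1)] += 1
    return GridOccurrenceMap(counts)


def grid_distance(n: tuple[int, int], m: tuple[int, int], metric: str = "manhattan") -> int:
    """Distance between grid cells: |dr| + |dc| (or Chebyshev max)."""
    dr, dc = abs(n[0] - m[0]), abs(n[1] - m[1])
    if metric == "manhattan":
        return dr + dc
    if metric == "chebyshev":
        return max(dr, dc)
    raise ValueError(f"unknown metric {metric!r}")


def _cell_distance_matrix(metric: str) -> np.ndarray:
    r, c = np.divmod(np.arange(GRID * GRID), GRID)
    dr = np.abs(r[:, None] - r[None, :])
    dc = np.abs(c[:, None] - c[None, :])
    return dr + dc if metric == "manhattan" else np.maximum(dr, dc)


def build_adjacency(
    occ: GridOccurrenceMap | np.ndarray, L_c: int, metric: str = "manhattan"
) -> AdjacencyMatrix:
    """Occurrence-adjacency matrix of one NSS in one image.

    For each pair of distinct cells both holding the NSS and closer than
    ``L_c``, the entry is the smaller of the two counts; the diagonal is
    forced to zero so the spectrum has zero trace.
    """
    if L_c < 1:
        raise ValueError("L_c must be >= 1")
    counts = occ.counts if isinstance(occ, GridOccurrenceMap) else np.asarray(occ)
    flat = counts.ravel().astype(float)  # row-major cell order 0..63
    D = _cell_distance_matrix(metric)
    occupied = flat > 0
    A = np.minimum(flat[:, None], flat[None, :])
    A[~(occupied[:, None] & occupied[None, :])] = 0
    A[D >= L_c] = 0
    np.fill_diagonal(A, 0)
    return AdjacencyMatrix(entries=A, L_c=L_c)


def spectral_feature(A: AdjacencyMatrix | np.ndarray, N_c: int) -> np.ndarray:
    """The N_c largest-magnitude eigenvalues, |value| descending.

    Symmetry makes the spectrum real; ties in magnitude break toward the
    positive (signed-descending) eigenvalue.  Short spectra are zero-padded.
    """
    M = A.entries if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("adjacency matrix must be symmetric")
    # rows/cols of unoccupied cells are zero: the nonzero spectrum lives on
    # the occupied-cell principal submatrix
    nz = np.flatnonzero(M.any(axis=0))
    if len(nz) == 0:
        return np.zeros(N_c)
    lam = np.linalg.eigvalsh(M[np.ix_(nz, nz)])
    order = np.lexsort((-lam, -np.abs(lam)))
    lam = lam[order][:N_c]
    out = np.zeros(N_c)
    out[: len(lam)] = lam
    return out


def adjacency_spectrum(
    counts: np.ndarray, L_c: int, N_c: int, metric: str = "manhattan"
) -> np.ndarray:
    """Fast path: spectral feature straight from an 8x8 count map."""
    flat = np.asarray(counts).ravel().astype(float)
    nz = np.flatnonzero(flat > 0)
    if len(nz) < 2:
        return np.zeros(N_c)
    sub = np.minimum(flat[nz][:, None], flat[nz][None, :])
    D = _cell_distance_matrix(metric)[np.ix_(nz, nz)]
    sub[D >= L_c] = 0
    np.fill_diagonal(sub, 0)
    if not sub.any():
        return np.zeros(N_c)
    lam = np.linalg.eigvalsh(sub)
    order = np.lexsort((-lam, -np.abs(lam)))
    lam = lam[order][:N_c]
    out = np.zeros(N_c)
    out[: len(lam)] = lam
    return out


def fisher_matrix(
    features: Mapping[object, np.ndarray], top_d: int = 3, eps: float = 1e-12
) -> pd.DataFrame:
    """Per-category-pair Fisher scores of one NSS's spectral features.

    ``features`` maps category -> (n_images, N_c) eigenvalue array.  The
    score for a pair is the sum over the first ``top_d`` dimensions of
    (mu_a - mu_b)^2 / (var_a + var_b + eps); identical class distributions
    score ~0 and labels can be swapped freely (symmetric, zero diagonal).
    Categories with no images get zero rows with a warning.
    """
    cats = list(features.keys())
    C = len(cats)
    scores = np.zeros((C, C))
    stats = {}
    for c in cats:
        X = np.asarray(features[c], dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(X) == 0:
            warnings.warn(f"category {c!r} has no images; zero Fisher row", stacklevel=2)
            stats[c] = None
            continue
        d = min(top_d, X.shape[1])
        stats[c] = (X[:, :d].mean(axis=0), X[:, :d].var(axis=0, ddof=1) if len(X) > 1
                    else np.zeros(d))
    for i, a in enumerate(cats):
        for j in range(i + 1, C):
            b = cats[j]
            if stats[a] is None or stats[b] is None:
                continue
            (ma, va), (mb, vb) = stats[a], stats[b]
            d = min(len(ma), len(mb))
            s = float(np.sum((ma[:d] - mb[:d]) ** 2 / (va[:d] + vb[:d] + eps)))
            scores[i, j] = scores[j, i] = s
    return pd.DataFrame(scores, index=cats, columns=cats)


def occurrence_matrix(
    image_categories: Mapping[str, object],
    image_source_categories: Mapping[str, Iterable[object]],
    categories: Sequence[object] | None = None,
) -> pd.DataFrame:
    """Row-normalized cross-category occurrence matrix.

    Entry (i, j) counts scenes of category j containing any NSS compiled
    from category i, then each row is divided by its diagonal element (so
    the diagonal is 1).  A zero diagonal leaves that row unnormalized with a
    warning.
    """
    if categories is None:
        categories = list(dict.fromkeys(image_categories.values()))
    pos = {c: i for i, c in enumerate(categories)}
    C = len(categories)
    M = np.zeros((C, C))
    for img, cat_j in image_categories.items():
        for cat_i in set(image_source_categories.get(img, ())):
            if cat_i in pos:
                M[pos[cat_i], pos[cat_j]] += 1
    for i in range(C):
        if M[i, i] > 0:
            M[i] /= M[i, i]
        else:
            warnings.warn(
                f"occurrence matrix diagonal is zero for {categories[i]!r}; "
                "row left unnormalized",
                stacklevel=2,
            )
    return pd.DataFrame(M, index=categories, columns=categories)
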