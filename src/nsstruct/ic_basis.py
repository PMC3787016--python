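"""ICA filter bank over circular patches, Gabor fits, and IC clustering.

Filters are learned per spatial scale with PCA-whitened FastICA and expressed
as analysis filters in pixel space, so the amplitude of filter A_j on a patch
P is the inner product P . A_j.  Each filter is then summarized by the
parameters of a best-fitting Gabor function; filters from all scales are
grouped into N clusters by orientation binning followed by K-means in the
canonicalized parameter space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .sampling import CircularPatch, build_circular_mask

__all__ = [
    "GaborParams",
    "ICFilter",
    "ICClusterSet",
    "learn_ica",
    "render_gabor",
    "fit_gabor",
    "canonicalize_gabor",
    "cluster_ics",
]

#: Gabor fits explaining less than this variance fraction go to the catch-all
#: cluster instead of polluting the parameter clusters.
UNFIT_R2 = 0.5

#: The six parameters used as the clustering space: four of the Gaussian
#: envelope and two of the sinusoid carrier.
CLUSTER_PARAM_NAMES = ("x0", "y0", "sx", "sy", "theta", "phi")


@dataclass(frozen=True)
class GaborParams:
    """Parameters of G(x,y) = amp * exp(-(x'^2/2sx^2 + y'^2/2sy^2)) * cos(2*pi*freq*x' + phi).

    (x', y') is (x - x0, y - y0) rotated by ``theta``; x = column index,
    y = row index of the filter's bounding square.  ``freq`` and ``amp`` are
    auxiliary (a full Gabor needs them) but are not clustering dimensions.
    """

    amp: float
    x0: float
    y0: float
    sx: float
    sy: float
    theta: float  # carrier orientation, canonical range [0, pi)
    freq: float  # cycles / pixel
    phi: float  # carrier phase, canonical range [0, 2*pi)
    r2: float = 0.0  # fraction of filter variance explained by the fit

    @property
    def unfit(self) -> bool:
        return self.r2 < UNFIT_R2

    def cluster_vector(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.sx, self.sy, self.theta, self.phi])


@dataclass
class ICFilter:
    """One ICA analysis filter (weights in pixel space, length l)."""

    weights: np.ndarray
    scale_index: int
    diameter: int
    gabor: GaborParams | None = None
    cluster_id: int | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights must be finite")


def learn_ica(
    patches, n_components: int, seed: int, max_iter: int = 500, tol: float = 1e-4,
    scale_index: int = 0, diameter: int | None = None,
) -> list[ICFilter]:
    """Learn ``n_components`` ICA analysis filters from patch vectors.

    ``patches`` is an (n, l) array or a list of :class:`CircularPatch`.
    The pipeline is: remove the dataset mean, whiten with PCA to
    ``n_components`` dimensions, run FastICA; the unmixing rows are returned
    in pixel space so amplitudes are plain inner products with patches.
    Deterministic given ``seed``.
    """
    if isinstance(patches, (list, tuple)) and patches and isinstance(patches[0], CircularPatch):
        if diameter is None:
            diameter = patches[0].diameter
        X = np.array([p.values for p in patches])
    else:
        X = np.asarray(patches, dtype=float)
    n, l = X.shape
    if n_components > l:
        raise ValueError(f"n_components={n_components} exceeds patch dimension {l}")
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds sample count {n}")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("patches have zero variance; cannot run ICA")
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("always", category=ConvergenceWarning)
        ica.fit(X)
    W = ica.components_  # amplitudes = (X - mean) @ W.T
    return [
        ICFilter(weights=W[j], scale_index=scale_index, diameter=diameter)
        for j in range(n_components)
    ]


def render_gabor(params: GaborParams, diameter: int) -> np.ndarray:
    """Evaluate the Gabor on the (d+1, d+1) bounding-square pixel grid."""
    size = diameter + 1
    y, x = np.mgrid[0:size, 0:size].astype(float)
    return _gabor_values(
        x, y,
        params.amp, params.x0, params.y0, params.sx, params.sy,
        params.theta, params.freq, params.phi,
    )


def _gabor_values(x, y, amp, x0, y0, sx, sy, theta, freq, phi):
    ct, st = np.cos(theta), np.sin(theta)
    xp = (x - x0) * ct + (y - y0) * st
    yp = -(x - x0) * st + (y - y0) * ct
    env = np.exp(-(xp**2 / (2 * sx**2) + yp**2 / (2 * sy**2)))
    return amp * env * np.cos(2 * np.pi * freq * xp + phi)


def _fft_init(square: np.ndarray) -> tuple[float, float, float]:
    """Initial (theta, freq, phi) from the dominant Fourier component."""
    size = square.shape[0]
    F = np.fft.fftshift(np.fft.fft2(square - square.mean()))
    c = size // 2
    mag = np.abs(F)
    mag[c, c] = 0  # ignore DC
    # search the upper half-plane only (conjugate symmetry)
    half = mag.copy()
    half[:c, :] = 0
    iy, ix = np.unravel_index(np.argmax(half), half.shape)
    ky, kx = (iy - c) / size, (ix - c) / size
    freq = float(np.hypot(kx, ky))
    theta = float(np.arctan2(ky, kx)) % np.pi
    phi = float(np.angle(F[iy, ix]))
    return theta, max(freq, 1e-3), phi


def _fit_r2(weights: np.ndarray, model: np.ndarray) -> float:
    ss_tot = np.sum((weights - weights.mean()) ** 2)
    if ss_tot <= 0:
        return 0.0
    return float(1.0 - np.sum((weights - model) ** 2) / ss_tot)


def fit_gabor(filt: ICFilter, n_extra_starts: int = 6) -> GaborParams:
    """Nonlinear least-squares Gabor fit on the filter's circular support.

    A Fourier-based initial guess (dominant orientation/frequency/phase) is
    refined together with a small multi-start sweep over coarse orientations
    and frequencies; the fit with the highest explained variance wins.
    Degenerate filters that defeat every start are returned with r2 = 0 and
    flagged unfit.
    """
    mask = build_circular_mask(filt.diameter)
    gm = mask.grid_mask()
    size = mask.bounding_size
    sq = np.zeros((size, size))
    sq[gm] = filt.weights
    y, x = np.mgrid[0:size, 0:size].astype(float)
    xm, ym, wm = x[gm], y[gm], filt.weights

    # envelope-centre init from energy centroid
    energy = wm**2
    tot = energy.sum()
    if tot <= 0:
        return GaborParams(0, size / 2, size / 2, size, size, 0.0, 0.0, 0.0, r2=0.0)
    cx = float((xm * energy).sum() / tot)
    cy = float((ym * energy).sum() / tot)
    s0 = filt.diameter / 4.0

    theta0, freq0, phi0 = _fft_init(sq)
    starts = [(theta0, freq0, phi0)]
    for k in range(n_extra_starts):
        th = np.pi * k / n_extra_starts
        starts.append((th, freq0, 0.0))
        starts.append((th, max(0.5 * freq0, 2.0 / size), 0.0))

    def residuals(p):
        amp, x0, y0, sx, sy, theta, freq, phi = p
        return _gabor_values(xm, ym, amp, x0, y0, sx, sy, theta, freq, phi) - wm

    amp0 = float(np.max(np.abs(wm)))
    best: GaborParams | None = None
    # rank starts cheaply by residual with amp/phase solved linearly
    ranked = []
    for theta, freq, phi in starts:
        ct, st = np.cos(theta), np.sin(theta)
        xp = (xm - cx) * ct + (ym - cy) * st
        yp = -(xm - cx) * st + (ym - cy) * ct
        env = np.exp(-(xp**2 + yp**2) / (2 * s0**2))
        D = np.column_stack([env * np.cos(2 * np.pi * freq * xp),
                             env * np.sin(2 * np.pi * freq * xp)])
        coef, res, *_ = np.linalg.lstsq(D, wm, rcond=None)
        sse = float(res[0]) if len(res) else float(np.sum((D @ coef - wm) ** 2))
        amp = float(np.hypot(*coef))
        ph = float(np.arctan2(-coef[1], coef[0]))
        ranked.append((sse, theta, freq, ph, amp))
    ranked.sort(key=lambda t: t[0])

    for sse, theta, freq, ph, amp in ranked[:3]:
        p0 = [amp if amp > 0 else amp0, cx, cy, s0, s0, theta, freq, ph]
        try:
            sol = least_squares(residuals, p0, method="lm", max_nfev=2000)
        except Exception:
            continue
        model = _gabor_values(xm, ym, *sol.x)
        r2 = _fit_r2(wm, model)
        cand = canonicalize_gabor(
            GaborParams(*[float(v) for v in sol.x], r2=r2)
        )
        if best is None or cand.r2 > best.r2:
            best = cand
    if best is None:
        best = GaborParams(0, cx, cy, size, size, 0.0, 0.0, 0.0, r2=0.0)
    return best


def canonicalize_gabor(params: GaborParams) -> GaborParams:
    """Map equivalent parameterizations to one canonical representative.

    Envelope scales to (0, +inf) by absolute value; orientation reduced
    mod pi (with the carrier phase negated for each pi reflection, since
    x' -> -x'); frequency made nonnegative (phase negated); amplitude made
    positive (phase shifted by pi); phase reduced mod 2*pi.  Rendering the
    result reproduces the input Gabor exactly.
    """
    amp, x0, y0 = params.amp, params.x0, params.y0
    sx, sy = abs(params.sx), abs(params.sy)
    theta, freq, phi = params.theta, params.freq, params.phi
    if freq < 0:
        freq, phi = -freq, -phi
    k = np.floor(theta / np.pi)
    theta = theta - k * np.pi
    if theta >= np.pi:  # rounding of a negative epsilon
        theta -= np.pi
        k += 1
    if int(k) % 2 != 0:
        phi = -phi
    if amp < 0:
        amp, phi = -amp, phi + np.pi
    phi = phi % (2 * np.pi)
    if phi >= 2 * np.pi:
        phi = 0.0
    return replace(
        params, amp=amp, x0=x0, y0=y0, sx=sx, sy=sy,
        theta=float(theta), freq=freq, phi=float(phi),
    )


@dataclass
class ICClusterSet:
    """ICA filters grouped into clusters of similar fitted Gabor parameters."""

    clusters: list[list[ICFilter]]
    n_orientation_bins: int
    centroids: np.ndarray  # (n_clusters, 6) mean parameter vectors (raw units)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def filters_matrix(self, scale_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Stacked filter weights at one scale plus their cluster indices.

        Returns ``(W, cluster_idx)`` with W of shape (m_total, l); clusters
        with no filter at this scale simply contribute no rows (their feature
        is defined as 0).
        """
        rows, idx = [], []
        for ci, cl in enumerate(self.clusters):
            for f in cl:
                if f.scale_index == scale_index:
                    rows.append(f.weights)
                    idx.append(ci)
        if not rows:
            return np.empty((0, 0)), np.array([], dtype=int)
        return np.array(rows), np.array(idx, dtype=int)


def _allocate(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder proportional allocation, >= 1 per nonempty bin."""
    alloc = np.zeros(len(counts), dtype=int)
    nonempty = counts > 0
    n_nonempty = int(nonempty.sum())
    if n_nonempty == 0:
        return alloc
    total = max(total, n_nonempty)
    quota = counts / counts.sum() * total
    alloc[nonempty] = np.maximum(1, np.floor(quota[nonempty]).astype(int))
    rem = quota - alloc
    while alloc.sum() < total:
        cand = np.where(nonempty & (alloc < counts))[0]
        if len(cand) == 0:
            break
        j = cand[np.argmax(rem[cand])]
        alloc[j] += 1
        rem[j] -= 1
    while alloc.sum() > total:
        cand = np.where(alloc > 1)[0]
        if len(cand) == 0:
            break
        j = cand[np.argmin(rem[cand])]
        alloc[j] -= 1
        rem[j] += 1
    return np.minimum(alloc, np.maximum(counts, 1))


def cluster_ics(
    filters: Sequence[ICFilter],
    n_orientation_bins: int = 16,
    clusters_per_bin_total: int = 100,
    seed: int = 0,
    restarts: int = 10,
) -> ICClusterSet:
    """Two-stage clustering of ICs across all scales.

    Stage 1 bins each fitted IC by carrier orientation into
    ``n_orientation_bins`` equal bins of [0, pi).  Stage 2 runs K-means
    within each bin on the z-scored 6-parameter vector, with per-bin cluster
    counts allocated proportionally to bin occupancy so the total is about
    ``clusters_per_bin_total``.  ICs whose Gabor fit is unfit go to one
    catch-all cluster appended last.
    """
    filters = list(filters)
    for f in filters:
        if f.gabor is None:
            raise ValueError("all filters must carry fitted Gabor parameters")
    fitted = [f for f in filters if not f.gabor.unfit]
    unfit = [f for f in filters if f.gabor.unfit]

    clusters: list[list[ICFilter]] = []
    if fitted:
        P = np.array([f.gabor.cluster_vector() for f in fitted])
        mu, sd = P.mean(axis=0), P.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (P - mu) / sd
        bin_width = np.pi / n_orientation_bins
        bins = np.clip(
            np.floor(P[:, 4] / bin_width).astype(int), 0, n_orientation_bins - 1
        )
        occupancy = np.bincount(bins, minlength=n_orientation_bins)
        alloc = _allocate(occupancy, clusters_per_bin_total)
        for b in range(n_orientation_bins):
            members = np.where(bins == b)[0]
            if len(members) == 0:
                continue
            k = int(alloc[b])
            if len(members) < k:
                warnings.warn(
                    f"orientation bin {b} has {len(members)} ICs < {k} requested "
                    "clusters; using one cluster per IC",
                    stacklevel=2,
                )
                k = len(members)
            # identical parameter vectors must land in one cluster
            _, inv = np.unique(Z[members].round(12), axis=0, return_inverse=True)
            n_unique = inv.max() + 1
            k = min(k, n_unique)
            if k == n_unique:
                labels = inv
            elif k == 1:
                labels = np.zeros(len(members), dtype=int)
            else:
                km = KMeans(
                    n_clusters=k, init="k-means++", n_init=restarts,
                    max_iter=300, tol=1e-4, random_state=(seed + b) % (2**31),
                )
                labels = km.fit_predict(Z[members])
            for c in range(labels.max() + 1):
                clusters.append([fitted[i] for i in members[labels == c]])
    if unfit:
        clusters.append(unfit)

    centroids = np.array(
        [np.mean([f.gabor.cluster_vector() for f in cl], axis=0) for cl in clusters]
    ) if clusters else np.empty((0, 6))
    for ci, cl in enumerate(clusters):
        for f in cl:
            f.cluster_id = ci
    return ICClusterSet(
        clusters=clusters,
        n_orientation_bins=n_orientation_bins,
        centroids=centroids,
    )
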