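"""Scene classification: 1-chi^2 kernel one-vs-rest C-SVM on NSS features.

Per-image feature vectors concatenate the L1-normalized occurrence
frequencies of the selected NSSs with each NSS's adjacency-spectrum
eigenvalues (min-max scaled to [0,1] on the training set, so the chi-square
kernel's nonnegativity requirement holds).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "chi2_kernel",
    "SceneFeatureScaler",
    "assemble_features",
    "TrainedModel",
    "train",
    "evaluate",
    "cross_validate",
    "pairwise_nss_accuracy",
    "ablation_run",
]


def chi2_kernel(X, Y=None, variant: str = "one_minus") -> np.ndarray:
    """1-chi^2 kernel: K(x, y) = 1 - sum_i (x_i - y_i)^2 / (x_i + y_i).

    Inputs must be nonnegative; terms with x_i + y_i = 0 contribute 0, so
    K(x, x) = 1 and K <= 1.  ``variant="half"`` applies the 1/2 factor used
    by some authors.  Accepts vectors or sample matrices and returns the
    Gram matrix (scalar for two vectors).
    """
    x = np.atleast_2d(np.asarray(X, dtype=float))
    scalar = np.asarray(X).ndim == 1 and (Y is None or np.asarray(Y).ndim == 1)
    y = x if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if np.any(x < -1e-12) or np.any(y < -1e-12):
        raise ValueError("chi-square kernel requires nonnegative features")
    diff2 = (x[:, None, :] - y[None, :, :]) ** 2
    denom = x[:, None, :] + y[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom > 0, diff2 / np.where(denom > 0, denom, 1.0), 0.0)
    dist = terms.sum(axis=2)
    if variant == "half":
        dist = 0.5 * dist
    elif variant != "one_minus":
        raise ValueError(f"unknown kernel variant {variant!r}")
    K = 1.0 - dist
    return float(K[0, 0]) if scalar else K


@dataclass
class SceneFeatureScaler:
    """Train-set min-max scaling of the spectral block to [0, 1].

    Frequencies are already nonnegative and L1-normalized per image; the
    eigenvalue columns can be negative, so each column is mapped affinely to
    [0, 1] using training-set extrema, with test values clipped.
    """

    lo: np.ndarray = None  # type: ignore[assignment]
    hi: np.ndarray = None  # type: ignore[assignment]

    def fit(self, spectral: np.ndarray) -> "SceneFeatureScaler":
        flat = spectral.reshape(len(spectral), -1)
        self.lo = flat.min(axis=0)
        self.hi = flat.max(axis=0)
        return self

    def transform(self, spectral: np.ndarray) -> np.ndarray:
        flat = spectral.reshape(len(spectral), -1)
        span = self.hi - self.lo
        span = np.where(span > 0, span, 1.0)
        return np.clip((flat - self.lo) / span, 0.0, 1.0)


def assemble_features(
    counts: np.ndarray,
    spectral: np.ndarray | None,
    scaler: SceneFeatureScaler | None = None,
) -> np.ndarray:
    """Per-image feature matrix for the chi-square SVM.

    ``counts`` is (n_images, K_sel) occurrence counts of the selected NSSs
    (fixed centroid order); ``spectral`` is (n_images, K_sel, N_c) eigenvalue
    blocks or None to drop spatial information.  The frequency block is
    L1-normalized per image (all-zero rows stay zero); the spectral block is
    scaled by ``scaler``.  Output dimensionality is K_sel*(1+N_c).
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    freq = np.divide(counts, np.where(totals > 0, totals, 1.0))
    if spectral is None:
        return freq
    if scaler is None:
        scaler = SceneFeatureScaler().fit(spectral)
    return np.hstack([freq, scaler.transform(np.asarray(spectral, dtype=float))])


@dataclass
class TrainedModel:
    """One-vs-rest C-SVM ensemble over a precomputed 1-chi^2 kernel."""

    classes: np.ndarray
    estimators: list[SVC]
    X_train: np.ndarray
    C: float
    kernel_variant: str = "one_minus"

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = chi2_kernel(np.atleast_2d(X), self.X_train, variant=self.kernel_variant)
        return np.column_stack([est.decision_function(K) for est in self.estimators])

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes[np.argmax(scores, axis=1)]  # ties -> lowest index


def train(
    X: np.ndarray, y: Sequence, C: float = 0.125, kernel_variant: str = "one_minus"
) -> TrainedModel:
    """Train the one-vs-rest ensemble on precomputed-kernel binary SVMs."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    X = np.asarray(X, dtype=float)
    K = chi2_kernel(X, variant=kernel_variant)
    ests = []
    for c in classes:
        est = SVC(kernel="precomputed", C=C)
        est.fit(K, (y == c).astype(int))
        ests.append(est)
    return TrainedModel(
        classes=classes, estimators=ests, X_train=X, C=C, kernel_variant=kernel_variant
    )


def evaluate(model: TrainedModel, X: np.ndarray, y: Sequence):
    """Row-normalized confusion matrix and mean per-class accuracy."""
    y = np.asarray(y)
    pred = model.predict(X)
    classes = model.classes
    cm = np.zeros((len(classes), len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y, pred):
        cm[pos[t], pos[p]] += 1
    rows = cm.sum(axis=1, keepdims=True)
    cm = np.divide(cm, np.where(rows > 0, rows, 1.0))
    present = rows.ravel() > 0
    mean_acc = float(np.mean(np.diag(cm)[present]))
    return pd.DataFrame(cm, index=classes, columns=classes), mean_acc


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < n_folds:
            warnings.warn(
                f"class {c!r} has {len(idx)} < {n_folds} samples; folds merged",
                stacklevel=3,
            )
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    return [np.array(sorted(f)) for f in folds if len(f)]


def cross_validate(
    y: Sequence,
    grid: Sequence[Mapping],
    fit_score_fn,
    n_folds: int = 5,
    seed: int = 0,
):
    """Five-fold CV grid search over pipeline parameters.

    ``fit_score_fn(params, train_idx, test_idx) -> accuracy`` refits
    everything downstream of the cached features for one grid point on the
    training indices and scores the held fold.  Returns
    ``(best_params, table)``; ties prefer the smallest C, then smallest M_c,
    then grid order.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng)
    all_idx = np.arange(len(y))
    rows = []
    for params in grid:
        accs = []
        for f in folds:
            train_idx = np.setdiff1d(all_idx, f)
            accs.append(fit_score_fn(params, train_idx, f))
        rows.append({**params, "cv_accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    best_i = sorted(
        range(len(rows)),
        key=lambda i: (
            -rows[i]["cv_accuracy"],
            rows[i].get("C", 0.0),
            rows[i].get("M_c", 0),
            i,
        ),
    )[0]
    return dict(grid[best_i]), table


def pairwise_nss_accuracy(
    freq: np.ndarray,
    spectral: np.ndarray,
    y: Sequence,
    categories: Sequence | None = None,
    train_fraction: float = 0.6,
    C: float = 0.125,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-NSS accuracy on every category pair from a 60/40 split.

    ``freq`` is (n_images, K) occurrence frequencies and ``spectral``
    (n_images, K, N_c) eigenvalues; each NSS contributes a (1 + N_c)-dim
    feature and the same chi-square SVM recipe is applied per pair.  Pair
    columns are ordered first-category-vs-rest, then second, etc.  An NSS
    absent from both categories of a pair scores chance (0.5).
    """
    y = np.asarray(y)
    if categories is None:
        categories = list(np.unique(y))
    rng = np.random.default_rng(seed)
    K = freq.shape[1]
    pairs = list(itertools.combinations(range(len(categories)), 2))
    acc = np.full((K, len(pairs)), 0.5)
    for pi, (a, b) in enumerate(pairs):
        idx = np.flatnonzero(np.isin(y, [categories[a], categories[b]]))
        tr_mask = np.zeros(len(idx), dtype=bool)
        for c in (categories[a], categories[b]):
            cidx = np.flatnonzero(y[idx] == c)
            n_tr = max(1, int(round(train_fraction * len(cidx))))
            tr_mask[rng.permutation(cidx)[:n_tr]] = True
        tr, te = idx[tr_mask], idx[~tr_mask]
        if len(te) == 0 or len(np.unique(y[tr])) < 2:
            continue
        for k in range(K):
            Xk = np.column_stack([freq[:, k : k + 1], spectral[:, k, :]])
            if not Xk[idx].any():
                continue
            scaler = SceneFeatureScaler().fit(Xk[tr][:, 1:][:, :, None])
            Xtr = np.hstack([Xk[tr][:, :1], scaler.transform(Xk[tr][:, 1:][:, :, None])])
            Xte = np.hstack([Xk[te][:, :1], scaler.transform(Xk[te][:, 1:][:, :, None])])
            try:
                model = train(Xtr, y[tr], C=C)
                acc[k, pi] = float(np.mean(model.predict(Xte) == y[te]))
            except ValueError:
                continue
    cols = [f"{categories[a]}|{categories[b]}" for a, b in pairs]
    return pd.DataFrame(acc, columns=cols)


def ablation_run(images, labels, profile, seed: int = 0, train_mask=None) -> pd.DataFrame:
    """Accuracy table with pipeline components disabled one at a time.

    Rows cover multi-scale vs best-single-scale and hexagon vs single
    central circle; columns cover with vs without adjacency spectra.  Thin
    wrapper over :class:`nsstruct.model.NSSModel` ablation refits.
    """
    from .model import NSSModel

    return NSSModel(images, labels, profile, train_mask=train_mask).ablations(seed=seed)
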