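"""Top-level modelling interface: NSSModel.fit() -> NSSResults.

The model is built from a labeled image collection plus a pipeline profile
and runs the full chain — dense hexagonal sampling, per-scale ICA, Gabor
clustering, per-category NSS codebooks, nearest-centroid assignment,
occurrence selection, adjacency-spectrum spatial features, and the
one-vs-rest 1-chi^2 SVM.  Test images never contribute to ICA, codebooks,
NSS selection, feature scaling, or cross-validation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from . import codebook as cb
from . import ic_basis, sampling, spatial
from .profiles import PipelineProfile

__all__ = ["NSSModel", "NSSResults"]


@dataclass
class _FeatureStage:
    """Cached per-image hex features plus the IC basis that produced them."""

    filters: list  # ICFilter, all scales
    cluster_set: ic_basis.ICClusterSet
    centers: list[np.ndarray]  # per image (n_locs, 2)
    cell_idx: list[np.ndarray]  # per image (n_locs,) flattened 8x8 cell
    features: list[dict[int, np.ndarray]]  # per image scale -> (n_locs, 7N)
    image_shapes: list[tuple[int, int]]
    seed: int


def _prepare_image(img, profile: PipelineProfile) -> np.ndarray:
    img = sampling.to_grayscale(np.asarray(img, dtype=float))
    if profile.max_long_edge is not None:
        img = sampling.resize_long_edge(img, profile.max_long_edge)
    return img


class NSSModel:
    """Scene-classification model over natural scene structures.

    Parameters
    ----------
    images : sequence of 2-D (or RGB) arrays
    labels : sequence of category labels, one per image
    profile : PipelineProfile
        All stage parameters; see :mod:`nsstruct.profiles`.
    train_mask : boolean array, optional
        Which images form the training set.  Defaults to a stratified 60/40
        split drawn at fit time.
    """

    def __init__(self, images, labels, profile: PipelineProfile, train_mask=None):
        self.images = list(images)
        self.labels = np.asarray(labels)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        self.profile = profile
        self.train_mask = None if train_mask is None else np.asarray(train_mask, bool)
        self._stage_cache: dict[int, _FeatureStage] = {}

    @classmethod
    def from_directory(cls, root, profile: PipelineProfile, train_mask=None):
        """Build from the ``root/<category>/<image>`` dataset layout.

        Files named ``train_*``/``test_*`` fix the split; otherwise pass or
        draw a ``train_mask``.
        """
        from pathlib import Path

        root = Path(root)
        images, labels, mask = [], [], []
        has_tags = False
        for cat_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for f in sorted(cat_dir.iterdir()):
                if f.suffix.lower() not in {".png", ".jpg", ".jpeg", ".pgm"}:
                    continue
                images.append(sampling.load_image(f))
                labels.append(cat_dir.name)
                if f.name.startswith(("train_", "test_")):
                    has_tags = True
                mask.append(f.name.startswith("train_"))
        if not images:
            raise ValueError(f"no images found under {root}")
        if train_mask is None and has_tags:
            train_mask = np.array(mask)
        return cls(images, labels, profile, train_mask=train_mask)

    # ------------------------------------------------------------------ stages

    def _split(self, seed: int) -> np.ndarray:
        if self.train_mask is not None:
            return self.train_mask
        rng = np.random.default_rng(seed)
        mask = np.zeros(len(self.images), dtype=bool)
        for c in np.unique(self.labels):
            idx = np.flatnonzero(self.labels == c)
            rng.shuffle(idx)
            mask[idx[: int(round(0.6 * len(idx)))]] = True
        return mask

    def _feature_stage(self, seed: int, train_mask: np.ndarray) -> _FeatureStage:
        """Sample, learn the IC basis on training images, project everything."""
        if seed in self._stage_cache:
            return self._stage_cache[seed]
        p = self.profile
        rng = np.random.default_rng(seed)
        n_scales = len(p.diameters)
        prepared = [_prepare_image(img, p) for img in self.images]

        # pass 1: pool training patches per scale for ICA
        pool: dict[int, list[np.ndarray]] = {si: [] for si in range(n_scales)}
        per_image_budget = max(
            1, p.ica_patches // max(int(train_mask.sum()), 1)
        )
        for i in np.flatnonzero(train_mask):
            _, arrays = sampling.sample_image_arrays(
                prepared[i], p.step, p.diameters, p.target_diameter
            )
            for si in range(n_scales):
                flat = arrays[si].reshape(-1, arrays[si].shape[-1])
                if len(flat) > per_image_budget:
                    sel = rng.choice(len(flat), per_image_budget, replace=False)
                    flat = flat[sel]
                pool[si].append(flat)

        filters: list[ic_basis.ICFilter] = []
        for si in range(n_scales):
            X = np.vstack(pool[si])
            if p.center_patches:
                X = X - X.mean(axis=1, keepdims=True)
            filters.extend(
                ic_basis.learn_ica(
                    X, p.n_ics, seed=(seed + 17 * si) % (2**31),
                    scale_index=si, diameter=p.target_diameter,
                )
            )
        for f in filters:
            f.gabor = ic_basis.fit_gabor(f)
        cluster_set = ic_basis.cluster_ics(
            filters,
            n_orientation_bins=p.n_orientation_bins,
            clusters_per_bin_total=p.n_ic_clusters,
            seed=seed,
            restarts=p.kmeans_restarts,
        )

        # pass 2: hex features for every image at every scale
        centers_all, cells_all, feats_all, shapes = [], [], [], []
        for img in prepared:
            centers, arrays = sampling.sample_image_arrays(
                img, p.step, p.diameters, p.target_diameter
            )
            h, w = img.shape
            cells = (
                np.minimum(centers[:, 0] * spatial.GRID // h, spatial.GRID - 1)
                * spatial.GRID
                + np.minimum(centers[:, 1] * spatial.GRID // w, spatial.GRID - 1)
            ) if len(centers) else np.empty(0, dtype=int)
            feats = {
                si: cb.batch_hex_features(
                    arrays[si], cluster_set, si, center_patches=p.center_patches
                ).astype(np.float32)
                for si in range(n_scales)
            }
            centers_all.append(centers)
            cells_all.append(cells)
            feats_all.append(feats)
            shapes.append((h, w))
        stage = _FeatureStage(
            filters=filters, cluster_set=cluster_set, centers=centers_all,
            cell_idx=cells_all, features=feats_all, image_shapes=shapes, seed=seed,
        )
        self._stage_cache[seed] = stage
        return stage

    @staticmethod
    def _effective_features(
        stage: _FeatureStage, profile: PipelineProfile
    ) -> list[dict[int, np.ndarray]]:
        """Apply the ablation switches (scale subset, single circle)."""
        n_scales_all = len(stage.features[0]) if stage.features else 0
        scales = (
            tuple(range(n_scales_all))
            if profile.use_scales is None
            else tuple(profile.use_scales)
        )
        N = stage.cluster_set.n_clusters
        out = []
        for feats in stage.features:
            d = {}
            for si in scales:
                F = feats[si]
                d[si] = F[:, :N] if not profile.hexagon else F
            out.append(d)
        return out

    def _codebook_stage(
        self,
        feats: list[dict[int, np.ndarray]],
        train_idx: np.ndarray,
        profile: PipelineProfile,
        seed: int,
    ):
        """Per-category codebooks from training images, pooled and selected."""
        rng = np.random.default_rng(seed + 101)
        cats = list(dict.fromkeys(self.labels[np.sort(train_idx)].tolist()))
        books = []
        for cat in cats:
            rows = []
            for i in train_idx:
                if self.labels[i] != cat:
                    continue
                for F in feats[i].values():
                    rows.append(F)
            X = np.vstack(rows) if rows else np.empty((0, 1))
            if len(X) > profile.codebook_samples:
                sel = rng.choice(len(X), profile.codebook_samples, replace=False)
                X = X[sel]
            K = min(profile.nss_per_category, len(X))
            books.append(
                cb.build_category_codebook(
                    np.asarray(X, dtype=float), K,
                    seed=(seed + hash(str(cat)) % 1000) % (2**31),
                    category=str(cat), restarts=profile.kmeans_restarts,
                )
            )
        book = cb.NSSCodebook.pool(books)

        assignments = [
            {si: cb.assign_nss(F, book) if len(F) else np.empty(0, int)
             for si, F in feats[i].items()}
            for i in range(len(feats))
        ]
        if profile.occurrence_threshold is not None:
            per_image = [
                (str(i), self.labels[i],
                 np.unique(np.concatenate([np.atleast_1d(a) for a in assignments[i].values()]))
                 if assignments[i] else [])
                for i in train_idx
            ]
            book = cb.select_nss(book, per_image, profile.occurrence_threshold)
        return book, assignments

    def _spatial_stage(
        self,
        assignments,
        cell_idx,
        book: cb.NSSCodebook,
        profile: PipelineProfile,
    ):
        """Counts and adjacency spectra of the selected NSSs per image."""
        sel_ids = np.flatnonzero(book.selected)
        pos = -np.ones(book.size, dtype=int)
        pos[sel_ids] = np.arange(len(sel_ids))
        n_img = len(assignments)
        counts = np.zeros((n_img, len(sel_ids)))
        spectra = np.zeros((n_img, len(sel_ids), profile.N_c))
        for i in range(n_img):
            cellmaps = np.zeros((len(sel_ids), spatial.GRID * spatial.GRID), dtype=int)
            for si, ids in assignments[i].items():
                ids = np.atleast_1d(ids)
                if not len(ids):
                    continue
                p = pos[ids]
                ok = p >= 0
                np.add.at(cellmaps, (p[ok], cell_idx[i][ok]), 1)
            counts[i] = cellmaps.sum(axis=1)
            for k in np.flatnonzero((cellmaps > 0).sum(axis=1) >= 2):
                spectra[i, k] = spatial.adjacency_spectrum(
                    cellmaps[k].reshape(spatial.GRID, spatial.GRID),
                    profile.L_c, profile.N_c, metric=profile.distance_metric,
                )
        return sel_ids, counts, spectra

    def _classify(
        self, counts, spectra, train_idx, test_idx, profile: PipelineProfile
    ):
        spec = spectra if profile.use_adjacency else None
        scaler = None
        if spec is not None:
            scaler = clf.SceneFeatureScaler().fit(spec[train_idx])
        X = clf.assemble_features(counts, spec, scaler=scaler)
        model = clf.train(
            X[train_idx], self.labels[train_idx],
            C=profile.C, kernel_variant=profile.kernel_variant,
        )
        cm, acc = clf.evaluate(model, X[test_idx], self.labels[test_idx])
        return model, scaler, X, cm, acc

    # --------------------------------------------------------------------- fit

    def fit(self, seed: int = 0, profile: PipelineProfile | None = None) -> "NSSResults":
        """Run the full pipeline; returns a results object."""
        t0 = time.perf_counter()
        p = profile or self.profile
        train_mask = self._split(seed)
        train_idx = np.flatnonzero(train_mask)
        test_idx = np.flatnonzero(~train_mask)
        stage = self._feature_stage(seed, train_mask)
        feats = self._effective_features(stage, p)
        book, assignments = self._codebook_stage(feats, train_idx, p, seed)
        sel_ids, counts, spectra = self._spatial_stage(
            assignments, stage.cell_idx, book, p
        )
        svm, scaler, X, cm, acc = self._classify(counts, spectra, train_idx, test_idx, p)
        return NSSResults(
            model=self, profile=p, seed=seed,
            train_idx=train_idx, test_idx=test_idx,
            cluster_set=stage.cluster_set, filters=stage.filters,
            nss_codebook=book, selected_ids=sel_ids,
            assignments=assignments, cell_idx=stage.cell_idx,
            counts=counts, spectra=spectra, features=X,
            svm=svm, scaler=scaler,
            confusion_matrix=cm, accuracy=acc,
            fit_seconds=time.perf_counter() - t0,
        )

    # --------------------------------------------------------- model selection

    def cross_validate(
        self, grid: Sequence[Mapping], n_folds: int = 5, seed: int = 0
    ):
        """Five-fold CV on the training images over a parameter grid.

        Grid keys may include ``C``, ``M_c``, ``L_c``, ``N_c`` and
        ``nss_per_category``; codebooks, selection, spatial features and the
        SVM are refit per fold from the training folds only.  Returns
        ``(best_params, table)``.
        """
        train_mask = self._split(seed)
        train_idx = np.flatnonzero(train_mask)
        stage = self._feature_stage(seed, train_mask)
        feats = self._effective_features(stage, self.profile)

        def fit_score(params, tr, te):
            prof = self.profile.replace(
                **{
                    {"M_c": "occurrence_threshold"}.get(k, k): v
                    for k, v in params.items()
                }
            )
            tr_g, te_g = train_idx[tr], train_idx[te]
            book, assign = self._codebook_stage(feats, tr_g, prof, seed)
            _, counts, spectra = self._spatial_stage(
                assign, stage.cell_idx, book, prof
            )
            spec = spectra if prof.use_adjacency else None
            scaler = clf.SceneFeatureScaler().fit(spec[tr_g]) if spec is not None else None
            X = clf.assemble_features(counts, spec, scaler=scaler)
            m = clf.train(X[tr_g], self.labels[tr_g], C=prof.C,
                          kernel_variant=prof.kernel_variant)
            return float(np.mean(m.predict(X[te_g]) == self.labels[te_g]))

        return clf.cross_validate(
            self.labels[train_idx], list(grid), fit_score, n_folds=n_folds, seed=seed
        )

    # -------------------------------------------------------------- ablations

    def ablations(self, seed: int = 0) -> pd.DataFrame:
        """Accuracy with components disabled, mirroring the published table.

        Rows: multi-scale hexagon, best single-scale hexagon, multi-scale
        single-circle.  Columns: with / without adjacency spectra.
        """
        n_scales = len(self.profile.diameters)
        rows = {}
        variants = {"multiscale_hexagon": self.profile}
        best_single = None
        for si in range(n_scales):
            v = self.profile.replace(use_scales=(si,))
            r = self.fit(seed=seed, profile=v)
            if best_single is None or r.accuracy > best_single[1].accuracy:
                best_single = (v, r)
        variants["best_single_scale_hexagon"] = best_single[0]
        variants["multiscale_single_circle"] = self.profile.replace(hexagon=False)
        for name, prof in variants.items():
            with_adj = self.fit(seed=seed, profile=prof.replace(use_adjacency=True))
            without = self.fit(seed=seed, profile=prof.replace(use_adjacency=False))
            rows[name] = {
                "with_adjacency": with_adj.accuracy,
                "without_adjacency": without.accuracy,
            }
        return pd.DataFrame(rows).T[["without_adjacency", "with_adjacency"]]


@dataclass
class NSSResults:
    """Fitted pipeline state, held-out performance, and diagnostics."""

    model: NSSModel
    profile: PipelineProfile
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    cluster_set: ic_basis.ICClusterSet
    filters: list
    nss_codebook: cb.NSSCodebook
    selected_ids: np.ndarray
    assignments: list
    cell_idx: list
    counts: np.ndarray  # (n_images, K_sel)
    spectra: np.ndarray  # (n_images, K_sel, N_c)
    features: np.ndarray  # (n_images, K_sel*(1+N_c)) final SVM features
    svm: clf.TrainedModel
    scaler: clf.SceneFeatureScaler | None
    confusion_matrix: pd.DataFrame
    accuracy: float  # mean per-class held-out accuracy
    fit_seconds: float = 0.0

    @property
    def labels(self) -> np.ndarray:
        return self.model.labels

    def gabor_fit_quality(self) -> np.ndarray:
        """r^2 of the Gabor fit for every IC filter."""
        return np.array([f.gabor.r2 for f in self.filters])

    def occurrence_matrix(self) -> pd.DataFrame:
        """Cross-category NSS occurrence matrix over the training images."""
        cats = {}
        srcs = {}
        for i in self.train_idx:
            img = str(i)
            cats[img] = self.labels[i]
            present = np.unique(
                np.concatenate(
                    [np.atleast_1d(a) for a in self.assignments[i].values()]
                )
            ) if self.assignments[i] else np.array([], int)
            present = present[self.nss_codebook.selected[present]]
            srcs[img] = set(self.nss_codebook.source_category[present].tolist())
        return spatial.occurrence_matrix(cats, srcs)

    def fisher_matrix(self, sel_pos: int, top_d: int | None = None) -> pd.DataFrame:
        """Fisher discriminant matrix of one selected NSS (training images)."""
        if top_d is None:
            top_d = min(self.profile.N_c, 5)
        feats = {
            c: self.spectra[self.train_idx][self.labels[self.train_idx] == c, sel_pos]
            for c in np.unique(self.labels)
        }
        return spatial.fisher_matrix(feats, top_d=top_d)

    def pairwise_nss_accuracy(self, seed: int | None = None) -> pd.DataFrame:
        """Per-NSS, per-category-pair accuracy on a 60/40 training-set split."""
        tr = self.train_idx
        totals = self.counts[tr].sum(axis=1, keepdims=True)
        freq = np.divide(self.counts[tr], np.where(totals > 0, totals, 1.0))
        return clf.pairwise_nss_accuracy(
            freq, self.spectra[tr], self.labels[tr],
            C=self.profile.C, seed=self.seed if seed is None else seed,
        )

    def summary(self) -> str:
        p = self.profile
        lines = [
            "NSS scene-classification results",
            "=" * 44,
            f"images: {len(self.labels)}  (train {len(self.train_idx)}, "
            f"test {len(self.test_idx)})",
            f"categories: {list(self.confusion_matrix.index)}",
            f"scales (diameters px): {p.diameters} -> common {p.target_diameter}",
            f"ICs/scale: {p.n_ics}   IC clusters: {self.cluster_set.n_clusters}",
            f"master book: {self.nss_codebook.size} NSSs, "
            f"{len(self.selected_ids)} selected "
            f"(M_c={p.occurrence_threshold})",
            f"spatial: 8x8 grid, L_c={p.L_c}, N_c={p.N_c} ({p.distance_metric})",
            f"SVM: one-vs-rest C-SVM, 1-chi^2 kernel, C={p.C}",
            "-" * 44,
            f"mean per-class held-out accuracy: {self.accuracy:.3f}",
            f"median Gabor fit r^2: {np.median(self.gabor_fit_quality()):.3f}",
            f"fit time: {self.fit_seconds:.1f} s",
            "-" * 44,
            "confusion matrix (rows = true, row-normalized):",
            self.confusion_matrix.round(3).to_string(),
        ]
        return "\n".join(lines)
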