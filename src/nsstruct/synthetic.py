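"""Seeded synthetic scene categories for end-to-end pipeline testing.

Categories are built so that class identity is carried both by local
oriented-texture content (exercising the occurrence-frequency features) and
by the spatial layout of that content (exercising the adjacency-eigenvalue
features).  Contrast sets isolate each channel: one varies only the
arrangement of identical textures, one only their layout dispersal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "TextureSpec",
    "RegionSpec",
    "SceneRecipe",
    "Benchmark",
    "render_scene",
    "make_benchmark",
    "make_contrast_set",
    "write_benchmark",
]


@dataclass(frozen=True)
class TextureSpec:
    """One texture: kind in {grating, oriented_noise, blobs, ramp, flat}.

    ``orientation_deg`` is the bar/stripe orientation (0 = horizontal bars,
    i.e. intensity varies along rows only); ``freq`` in cycles/pixel;
    ``contrast`` is the peak amplitude around the 0.5 background.
    """

    kind: str
    orientation_deg: float = 0.0
    freq: float = 0.125
    contrast: float = 0.4
    blob_sigma: float = 3.0
    blob_density: float = 0.004


@dataclass(frozen=True)
class RegionSpec:
    """Where a texture goes: layout in {full, band, rect, scatter, center, mixband}.

    ``band``: top fraction ``frac`` of the image.  ``rect``: one block of
    fractional bounds ``bounds`` = (r0, r1, c0, c1).  ``scatter``: ``n_spots``
    square spots of side ``spot`` pixels at seeded random positions.
    ``center``: a centred disk of fractional radius ``frac``.  ``mixband``:
    full-field smooth sinusoidal blend between ``texture`` and ``texture2``
    along ``axis`` ("row" or "col") with the given pixel ``period`` — no hard
    boundaries, so small patches cannot tell the blend direction.
    """

    layout: str
    texture: TextureSpec
    frac: float = 0.4
    bounds: tuple[float, float, float, float] = (0.0, 0.5, 0.0, 0.5)
    n_spots: int = 8
    spot: int = 32
    texture2: TextureSpec | None = None
    axis: str = "row"
    period: float = 128.0


@dataclass(frozen=True)
class SceneRecipe:
    """Fully determines one image given its seed."""

    category: str
    regions: tuple[RegionSpec, ...]
    noise_sigma: float = 0.02
    size: tuple[int, int] = (256, 256)
    seed: int = 0
    background: TextureSpec = field(
        default_factory=lambda: TextureSpec(kind="flat", contrast=0.0)
    )


def _texture_field(spec: TextureSpec, shape, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    th = np.deg2rad(spec.orientation_deg)
    # coordinate perpendicular to the bars: orientation 0 -> varies along rows
    u = rows * np.cos(th) - cols * np.sin(th)
    if spec.kind == "flat":
        return np.full(shape, 0.5)
    if spec.kind == "ramp":
        return 0.5 + spec.contrast * (u - u.mean()) / max(np.ptp(u), 1)
    if spec.kind == "grating":
        phase = rng.uniform(0, 2 * np.pi)
        return 0.5 + spec.contrast * np.cos(2 * np.pi * spec.freq * u + phase)
    if spec.kind == "oriented_noise":
        noise = rng.standard_normal(shape)
        fr = np.fft.fftfreq(h)[:, None]
        fc = np.fft.fftfreq(w)[None, :]
        # stripes at orientation th vary along direction (cos th, -sin th)
        fu = fr * np.cos(th) - fc * np.sin(th)
        fv = fr * np.sin(th) + fc * np.cos(th)
        bw_r, bw_t = spec.freq / 2.5, spec.freq / 2.5
        H = np.exp(-((np.abs(fu) - spec.freq) ** 2) / (2 * bw_r**2))
        H *= np.exp(-(fv**2) / (2 * bw_t**2))
        filt = np.real(np.fft.ifft2(np.fft.fft2(noise) * H))
        sd = filt.std()
        if sd > 0:
            filt = filt / sd
        return 0.5 + spec.contrast * 0.5 * filt
    if spec.kind == "blobs":
        field_ = np.zeros(shape)
        n = max(1, int(spec.blob_density * h * w))
        rr = rng.integers(0, h, n)
        cc = rng.integers(0, w, n)
        signs = rng.choice([-1.0, 1.0], n)
        field_[rr, cc] = signs
        field_ = gaussian_filter(field_, spec.blob_sigma)
        sd = field_.std()
        if sd > 0:
            field_ = field_ / sd
        return 0.5 + spec.contrast * 0.5 * field_
    raise ValueError(f"unknown texture kind {spec.kind!r}")


def _region_mask(spec: RegionSpec, shape, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    m = np.zeros(shape, dtype=bool)
    if spec.layout == "full":
        m[:] = True
    elif spec.layout == "band":
        m[: int(spec.frac * h)] = True
    elif spec.layout == "rect":
        r0, r1, c0, c1 = spec.bounds
        m[int(r0 * h) : int(r1 * h), int(c0 * w) : int(c1 * w)] = True
    elif spec.layout == "scatter":
        s = spec.spot
        for _ in range(spec.n_spots):
            r = int(rng.integers(0, max(h - s, 1)))
            c = int(rng.integers(0, max(w - s, 1)))
            m[r : r + s, c : c + s] = True
    elif spec.layout == "center":
        rows, cols = np.mgrid[0:h, 0:w]
        rad = spec.frac * min(h, w) / 2
        m[(rows - h / 2) ** 2 + (cols - w / 2) ** 2 <= rad**2] = True
    else:
        raise ValueError(f"unknown layout {spec.layout!r}")
    return m


def render_scene(recipe: SceneRecipe) -> np.ndarray:
    """Composite the recipe's textured regions; deterministic given the seed."""
    rng = np.random.default_rng(recipe.seed)
    img = _texture_field(recipe.background, recipe.size, rng)
    for region in recipe.regions:
        if region.layout == "mixband":
            h, w = recipe.size
            u = (np.arange(h)[:, None] if region.axis == "row"
                 else np.arange(w)[None, :])
            phase = rng.uniform(0, 2 * np.pi)
            wgt = 0.5 * (1 + np.cos(2 * np.pi * u / region.period + phase))
            wgt = np.broadcast_to(wgt, recipe.size)
            f1 = _texture_field(region.texture, recipe.size, rng)
            f2 = _texture_field(region.texture2, recipe.size, rng)
            img = wgt * f1 + (1 - wgt) * f2
            continue
        mask = _region_mask(region, recipe.size, rng)
        tex = _texture_field(region.texture, recipe.size, rng)
        img = np.where(mask, tex, img)
    if recipe.noise_sigma > 0:
        img = img + recipe.noise_sigma * rng.standard_normal(recipe.size)
    return np.clip(img, 0.0, 1.0)


@dataclass
class Benchmark:
    """A labeled synthetic image set with a fixed train/test split."""

    images: list[np.ndarray]
    labels: np.ndarray
    is_train: np.ndarray
    recipes: list[SceneRecipe]

    @property
    def categories(self) -> list:
        return list(dict.fromkeys(self.labels.tolist()))


def _default_recipes(size) -> dict[str, tuple[RegionSpec, ...]]:
    horiz = TextureSpec("oriented_noise", orientation_deg=0.0, freq=0.14, contrast=0.45)
    vert = TextureSpec("oriented_noise", orientation_deg=90.0, freq=0.14, contrast=0.45)
    blobs = TextureSpec("blobs", contrast=0.5, blob_sigma=3.0, blob_density=0.004)
    ramp = TextureSpec("ramp", orientation_deg=0.0, contrast=0.25)
    return {
        # A: horizontal texture concentrated in the top band over a ramp
        "bandscape": (
            RegionSpec("full", ramp),
            RegionSpec("band", horiz, frac=0.45),
        ),
        # B: vertical texture dispersed in scattered spots over a flat field
        "pillars": (
            RegionSpec("full", TextureSpec("flat")),
            RegionSpec("scatter", vert, n_spots=10, spot=40),
        ),
        # C: isotropic blob field clustered at the centre
        "blobfield": (
            RegionSpec("full", TextureSpec("flat")),
            RegionSpec("center", blobs, frac=0.62),
        ),
    }


def make_benchmark(
    n_categories: int = 3,
    n_per_category: int = 40,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
    train_fraction: float = 0.6,
    noise_sigma: float = 0.02,
) -> Benchmark:
    """Default 3-category benchmark with exact label balance.

    Categories differ in both oriented-texture content and spatial layout;
    the train/test split is stratified and deterministic given ``seed``.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    base = _default_recipes(size)
    names = list(base.keys())
    if n_categories > len(names):
        raise ValueError(f"at most {len(names)} built-in categories")
    names = names[:n_categories]
    rng = np.random.default_rng(seed)
    images, labels, is_train, recipes = [], [], [], []
    n_train = int(round(train_fraction * n_per_category))
    for cat in names:
        for k in range(n_per_category):
            recipe = SceneRecipe(
                category=cat,
                regions=base[cat],
                noise_sigma=noise_sigma,
                size=size,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            recipes.append(recipe)
            images.append(render_scene(recipe))
            labels.append(cat)
            is_train.append(k < n_train)
    return Benchmark(
        images=images,
        labels=np.array(labels),
        is_train=np.array(is_train),
        recipes=recipes,
    )


def make_contrast_set(
    kind: str,
    n_per_category: int = 24,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
    train_fraction: float = 0.6,
) -> Benchmark:
    """Two-category sets isolating one feature channel.

    ``kind="satellite"``: both categories smoothly blend the same two
    isotropic blob textures (coarse and fine); only the blend axis —
    horizontal vs vertical bands — differs.  A single circular patch sees
    some mixture level with the same distribution in both categories; only
    the hexagon's satellites, which straddle the blend gradient, reveal its
    direction.

    ``kind="layout"``: both categories contain four identical isolated
    texture spots whose pairwise gaps always exceed the hexagon span, so
    the local feature statistics (hence NSS occurrence frequencies) match;
    in one category the spots form a chain with grid-cell gaps below the
    adjacency threshold, in the other they sit near the image corners, so
    only the adjacency spectra separate the classes.  Built on 384x384
    images; analyse with ``distance_metric="chebyshev"`` and L_c = 3.
    """
    coarse = TextureSpec("blobs", contrast=0.5, blob_sigma=4.0, blob_density=0.003)
    fine = TextureSpec("blobs", contrast=0.5, blob_sigma=1.5, blob_density=0.02)
    tex = TextureSpec("oriented_noise", orientation_deg=45.0, freq=0.14, contrast=0.45)
    rng = np.random.default_rng(seed)
    images, labels, is_train, recipes = [], [], [], []
    n_train = int(round(train_fraction * n_per_category))
    if kind == "satellite":
        for cat, axis in (("hbands", "row"), ("vbands", "col")):
            for k in range(n_per_category):
                regions = (
                    RegionSpec("mixband", coarse, texture2=fine, axis=axis,
                               period=128.0),
                )
                recipes.append(
                    SceneRecipe(cat, regions, 0.02, size,
                                int(rng.integers(0, 2**31 - 1)))
                )
                images.append(render_scene(recipes[-1]))
                labels.append(cat)
                is_train.append(k < n_train)
    elif kind == "layout":
        size = (384, 384)
        h, w = size
        spot = 32
        for cat in ("clustered", "dispersed"):
            for k in range(n_per_category):
                if cat == "clustered":
                    pts = _chain_positions(rng, box=(76, 276), n=4,
                                           step=(108, 128), min_sep=108)
                else:
                    # jitter kept small so every pairwise gap stays >= 3 grid
                    # cells (no adjacency links) in the dispersed class
                    anchors = [(86, 86), (86, 266), (266, 86), (266, 266)]
                    pts = [
                        (int(a + rng.integers(-2, 3)), int(b + rng.integers(-2, 3)))
                        for a, b in anchors
                    ]
                regions = [RegionSpec("full", TextureSpec("flat"))]
                for r, c in pts:
                    regions.append(
                        RegionSpec(
                            "rect", tex,
                            bounds=(r / h, (r + spot) / h, c / w, (c + spot) / w),
                        )
                    )
                recipes.append(
                    SceneRecipe(cat, tuple(regions), 0.02, size,
                                int(rng.integers(0, 2**31 - 1)))
                )
                images.append(render_scene(recipes[-1]))
                labels.append(cat)
                is_train.append(k < n_train)
    else:
        raise ValueError(f"unknown contrast kind {kind!r}")
    return Benchmark(
        images=images,
        labels=np.array(labels),
        is_train=np.array(is_train),
        recipes=recipes,
    )


def _chain_positions(
    rng: np.random.Generator,
    box: tuple[int, int],
    n: int,
    step: tuple[float, float],
    min_sep: float,
    max_restarts: int = 50,
) -> list[tuple[int, int]]:
    """Spot top-left corners forming a chain with bounded consecutive steps.

    Every pair keeps distance >= min_sep; consecutive spots stay within
    ``step`` of each other.  Falls back to a jittered zigzag if rejection
    sampling fails.
    """
    lo, hi = box
    for _ in range(max_restarts):
        pts = [(int(rng.integers(lo, hi)), int(rng.integers(lo, hi)))]
        ok = True
        for _k in range(n - 1):
            placed = False
            for _try in range(60):
                ang = rng.uniform(0, 2 * np.pi)
                d = rng.uniform(*step)
                p = (int(pts[-1][0] + d * np.sin(ang)), int(pts[-1][1] + d * np.cos(ang)))
                if not (lo <= p[0] <= hi and lo <= p[1] <= hi):
                    continue
                if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in pts):
                    pts.append(p)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    # deterministic square fallback: consecutive steps 120, all pairs >= 120
    return [(lo, lo), (lo, lo + 120), (lo + 120, lo + 120), (lo + 120, lo)]


def write_benchmark(bench: Benchmark, out_dir, fmt: str = "png") -> None:
    """Write the directory-per-category layout consumed by the sampler."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    counters: dict[str, int] = {}
    for img, label, tr in zip(bench.images, bench.labels, bench.is_train):
        d = out / str(label)
        d.mkdir(parents=True, exist_ok=True)
        i = counters.get(label, 0)
        counters[label] = i + 1
        tag = "train" if tr else "test"
        iio.imwrite(d / f"{tag}_{i:03d}.{fmt}", (img * 255).astype(np.uint8))
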