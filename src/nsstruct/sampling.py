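"""Dense hexagonal sampling of circular image patches at multiple scales.

Seven non-overlapping circular patches — one central, six satellites at the
vertices of a regular hexagon of side equal to the patch diameter — are
extracted on a regular grid of image locations.  Larger scales are
down-sampled with bicubic interpolation so every scale shares the pixel
dimensionality of the smallest diameter.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "CircularMask",
    "HexConfiguration",
    "CircularPatch",
    "HexSample",
    "build_circular_mask",
    "hex_centers",
    "sample_image",
    "sample_image_arrays",
    "normalize_scale",
    "resize_long_edge",
    "to_grayscale",
    "load_image",
]

#: Rec.601 luma weights used for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CircularMask:
    """Pixel membership of a circular patch of a given even diameter.

    A pixel offset (row, col) from the patch centre belongs to the mask iff
    row^2 + col^2 <= (diameter/2)^2 (closed disk).  ``l`` is the number of
    member pixels and is identical for all patches of this diameter.
    """

    diameter: int
    member_offsets: np.ndarray  # (l, 2) int offsets, row-major sorted
    l: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "l", len(self.member_offsets))

    @property
    def bounding_size(self) -> int:
        return self.diameter + 1  # offsets span [-d/2, d/2]

    def grid_mask(self) -> np.ndarray:
        """Boolean (d+1, d+1) array of the disk on its bounding square."""
        r = self.diameter // 2
        m = np.zeros((self.bounding_size, self.bounding_size), dtype=bool)
        m[self.member_offsets[:, 0] + r, self.member_offsets[:, 1] + r] = True
        return m


@functools.lru_cache(maxsize=None)
def build_circular_mask(diameter: int) -> CircularMask:
    """Deterministic circular mask for an even ``diameter`` >= 4.

    Offsets are sorted row-major; two calls with the same diameter return
    identical masks.
    """
    if diameter < 4:
        raise ValueError(f"diameter must be >= 4, got {diameter}")
    if diameter % 2 != 0:
        raise ValueError(f"diameter must be even, got {diameter}")
    r = diameter // 2
    rows, cols = np.mgrid[-r : r + 1, -r : r + 1]
    inside = rows**2 + cols**2 <= r**2
    offsets = np.column_stack([rows[inside], cols[inside]])
    # mgrid iterates row-major already; make the sort explicit anyway
    order = np.lexsort((offsets[:, 1], offsets[:, 0]))
    offsets = offsets[order]
    offsets.setflags(write=False)
    return CircularMask(diameter=diameter, member_offsets=offsets)


def hex_centers(
    center: tuple[int, int], diameter: int, orientation_deg: float = 0.0
) -> np.ndarray:
    """Centres of the six satellite circles around ``center``.

    Satellites sit at angles ``orientation_deg + k*60`` (k = 0..5) at radius
    equal to ``diameter`` (tangent, non-overlapping circles), rounded to the
    nearest integer pixel.  Angle 0 points along the +col axis.
    """
    angles = np.deg2rad(orientation_deg + 60.0 * np.arange(6))
    drow = np.rint(diameter * np.sin(angles)).astype(int)
    dcol = np.rint(diameter * np.cos(angles)).astype(int)
    return np.column_stack([center[0] + drow, center[1] + dcol])


@dataclass(frozen=True)
class HexConfiguration:
    """One hexagonal configuration: a centre plus six satellite circles."""

    center: tuple[int, int]
    scale_index: int
    diameter: int
    satellite_centers: np.ndarray  # (6, 2)

    @property
    def all_centers(self) -> np.ndarray:
        return np.vstack([np.asarray(self.center)[None, :], self.satellite_centers])


@dataclass
class CircularPatch:
    """Masked gray intensities of one circular patch.

    ``values`` is the row vector P of length ``l`` used in the IC-cluster
    projection.  ``square`` keeps the full bounding square so that bicubic
    rescaling remains well defined.
    """

    values: np.ndarray
    scale_index: int
    source: tuple = ("", (0, 0))
    diameter: int | None = None
    square: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("patch intensities must be finite")
        if self.diameter is not None:
            mask = build_circular_mask(self.diameter)
            if len(self.values) != mask.l:
                raise ValueError(
                    f"expected {mask.l} values for diameter {self.diameter}, "
                    f"got {len(self.values)}"
                )

    def bounding_square(self) -> np.ndarray:
        """The patch on its bounding square; off-disk pixels take the patch mean."""
        if self.square is not None:
            return self.square
        mask = build_circular_mask(self.diameter)
        sq = np.full((mask.bounding_size,) * 2, self.values.mean())
        sq[mask.grid_mask()] = self.values
        return sq


@dataclass
class HexSample:
    """All patches of one hexagonal configuration at every sampled scale."""

    center: tuple[int, int]
    configurations: list[HexConfiguration]
    patches: dict[int, list[CircularPatch]]  # scale_index -> 7 patches


def _margin(diameter: int) -> int:
    # satellites lie at distance `diameter` from the centre, each of radius d/2
    return diameter + diameter // 2


def _grid_centers(shape: tuple[int, int], step: int, margin: int) -> np.ndarray:
    h, w = shape
    rows = np.arange(margin, h - margin, step)
    cols = np.arange(margin, w - margin, step)
    if len(rows) == 0 or len(cols) == 0:
        return np.empty((0, 2), dtype=int)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


@functools.lru_cache(maxsize=8)
def _resize_operator(src_diameter: int, dst_diameter: int) -> np.ndarray:
    """Linear operator performing bicubic resize of a bounding square.

    Bicubic interpolation is linear in pixel values, so resizing n patches is
    one matrix product.  Built once per (src, dst) pair by resizing the basis
    images.
    """
    s = src_diameter + 1
    d = dst_diameter + 1
    op = np.empty((d * d, s * s))
    basis = np.zeros((s, s))
    for i in range(s * s):
        basis.flat[i] = 1.0
        out = _sk_resize(basis, (d, d), order=3, mode="reflect",
                         anti_aliasing=False, clip=False)
        op[:, i] = out.ravel()
        basis.flat[i] = 0.0
    return op


def normalize_scale(patch: CircularPatch, target_diameter: int) -> CircularPatch:
    """Resample a patch to ``target_diameter`` with bicubic interpolation.

    The bounding square is resized and then re-masked with the target-diameter
    disk, so the output vector has the target l.  Patches already at the
    target diameter are returned unchanged; upsampling is refused.
    """
    if patch.diameter is None:
        raise ValueError("patch has no diameter metadata")
    if patch.diameter < target_diameter:
        raise ValueError(
            f"cannot upsample patch of diameter {patch.diameter} to {target_diameter}"
        )
    if patch.diameter == target_diameter:
        return patch
    op = _resize_operator(patch.diameter, target_diameter)
    sq = op @ patch.bounding_square().ravel()
    d = target_diameter + 1
    sq = sq.reshape(d, d)
    mask = build_circular_mask(target_diameter)
    return CircularPatch(
        values=sq[mask.grid_mask()],
        scale_index=patch.scale_index,
        source=patch.source,
        diameter=target_diameter,
        square=sq,
    )


def _extract_squares(image: np.ndarray, centers: np.ndarray, diameter: int) -> np.ndarray:
    """(n, d+1, d+1) bounding squares around integer ``centers``."""
    r = diameter // 2
    off = np.arange(-r, r + 1)
    rows = centers[:, 0, None, None] + off[None, :, None]
    cols = centers[:, 1, None, None] + off[None, None, :]
    return image[rows, cols]


def sample_image_arrays(
    image: np.ndarray,
    step: int,
    diameters: Sequence[int],
    target_diameter: int | None = None,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Vectorized dense sampling.

    Returns ``(centers, patches)`` where ``centers`` is (n, 2) and
    ``patches[scale_index]`` is an (n, 7, l) array of masked patch vectors,
    all rescaled to ``target_diameter`` (default: the smallest diameter).
    The grid is restricted to the region where the largest-diameter hexagon
    fits, so every location carries every scale.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = to_grayscale(image)
    diameters = sorted(diameters)
    if target_diameter is None:
        target_diameter = diameters[0]
    margin = max(_margin(d) for d in diameters)
    centers = _grid_centers(image.shape, step, margin)
    if len(centers) == 0:
        warnings.warn(
            f"image of shape {image.shape} too small for a hexagon of diameter "
            f"{max(diameters)}; no samples extracted",
            stacklevel=2,
        )
        return centers, {i: np.empty((0, 7, build_circular_mask(target_diameter).l))
                         for i in range(len(diameters))}
    out: dict[int, np.ndarray] = {}
    tmask = build_circular_mask(target_diameter)
    for si, d in enumerate(diameters):
        sat_off = hex_centers((0, 0), d) - 0  # offsets from centre
        all_centers = np.concatenate(
            [centers[:, None, :], centers[:, None, :] + sat_off[None, :, :]], axis=1
        )  # (n, 7, 2)
        flat = all_centers.reshape(-1, 2)
        sq = _extract_squares(image, flat, d)  # (7n, d+1, d+1)
        if d != target_diameter:
            op = _resize_operator(d, target_diameter)
            sq = (sq.reshape(len(flat), -1) @ op.T).reshape(
                len(flat), target_diameter + 1, target_diameter + 1
            )
        vals = sq[:, tmask.grid_mask()]  # (7n, l)
        out[si] = vals.reshape(len(centers), 7, tmask.l)
    return centers, out


def sample_image(
    image: np.ndarray,
    step: int,
    diameters: Sequence[int],
    target_diameter: int | None = None,
    image_id: str = "",
) -> list[HexSample]:
    """Object-level dense sampling (wraps :func:`sample_image_arrays`).

    Every returned sample has exactly 7 patches per scale, all rescaled to a
    common diameter; sampling is deterministic.
    """
    diameters = sorted(diameters)
    if target_diameter is None:
        target_diameter = diameters[0]
    centers, arrays = sample_image_arrays(image, step, diameters, target_diameter)
    samples = []
    for i, c in enumerate(centers):
        c = (int(c[0]), int(c[1]))
        configs = []
        patches: dict[int, list[CircularPatch]] = {}
        for si, d in enumerate(diameters):
            configs.append(
                HexConfiguration(
                    center=c,
                    scale_index=si,
                    diameter=d,
                    satellite_centers=hex_centers(c, d),
                )
            )
            patches[si] = [
                CircularPatch(
                    values=arrays[si][i, k],
                    scale_index=si,
                    source=(image_id, c),
                    diameter=target_diameter,
                )
                for k in range(7)
            ]
        samples.append(HexSample(center=c, configurations=configs, patches=patches))
    return samples


def resize_long_edge(image: np.ndarray, max_long_edge: int) -> np.ndarray:
    """Resize so the longer dimension equals ``max_long_edge``, keeping aspect.

    Images already at or below the target are returned unchanged.
    """
    image = np.asarray(image, dtype=float)
    long_edge = max(image.shape[:2])
    if long_edge <= max_long_edge:
        return image
    scale = max_long_edge / long_edge
    new_shape = tuple(int(round(s * scale)) for s in image.shape[:2])
    return _sk_resize(image, new_shape, order=3, mode="reflect", anti_aliasing=True)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB(A) -> gray with Rec.601 luma weights; gray input passes through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    return image[..., :3] @ _LUMA


def load_image(path) -> np.ndarray:
    """Read a raster image (PNG/JPEG/PGM) as float gray in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return to_grayscale(arr)
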