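"""Interpolated image fields and boundary point clouds.

An image (2-D raster or 3-D volume) is represented as a node-centred
lattice of coefficients with multilinear (bilinear / trilinear)
interpolation, so the source and target indicator functions S1(X), S2(x)
can be evaluated at arbitrary physical coordinates.  Boundary point
clouds extracted from the 0.5 iso-contour back the distance gate used by
the corrector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "IntensityField", "BoundaryCloud",
    "build_field", "sample", "sample_with_gradient",
    "extract_boundary", "distance", "smoothed",
]


@dataclass
class IntensityField:
    """Scalar (or per-channel RGB) coefficients on a regular lattice.

    ``coefficients`` has shape ``grid_shape`` for scalar fields or
    ``grid_shape + (3,)`` for RGB.  Physical coordinates of lattice node
    ``i`` are ``origin + i * spacing``; axis ``a`` of the array is
    physical axis ``a`` (no row/column flipping).
    """

    coefficients: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    n_channels: int = 1
    padding: str = "zero"       # out-of-lattice behaviour: "zero" | "clamp"

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        self.origin = np.atleast_1d(np.asarray(self.origin, dtype=np.float64))
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=np.float64))
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive per axis")
        if self.n_channels not in (1, 3):
            raise ValueError("n_channels must be 1 or 3")

    @property
    def ndim(self) -> int:
        return self.origin.size

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.coefficients.shape[:self.ndim]

    @property
    def bounds(self) -> list[tuple[float, float]]:
        hi = self.origin + (np.array(self.grid_shape) - 1) * self.spacing
        return [(float(lo), float(h)) for lo, h in zip(self.origin, hi)]

    def scalar_view(self) -> np.ndarray:
        """Channel-averaged coefficients (used for contouring)."""
        if self.n_channels == 1:
            return self.coefficients
        return self.coefficients.mean(axis=-1)


@dataclass
class BoundaryCloud:
    """Finite point sample of a deformed boundary, with a KD-tree index."""

    points: np.ndarray
    source_level: float = 0.5
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[0] == 0:
            raise ValueError("boundary cloud must be nonempty")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("boundary cloud contains non-finite points")

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def transformed(self, mapper) -> "BoundaryCloud":
        return BoundaryCloud(mapper(self.points), self.source_level)


# ---------------------------------------------------------------------------
# construction

def build_field(raster: np.ndarray, origin, spacing,
                binarize_threshold: float | None = None,
                padding: str = "zero") -> IntensityField:
    """Wrap a pixel/voxel raster as an interpolated field on [0, 1].

    Values are rescaled to [0, 1] by the raster maximum (8-bit images
    divide by 255); with ``binarize_threshold`` the coefficients become
    a crisp indicator in {0, 1}.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("zero-size raster rejected")
    raster = raster.astype(np.float64)
    if not np.all(np.isfinite(raster)):
        raise ValueError("raster contains non-finite values")
    n_channels = 1
    origin = np.atleast_1d(np.asarray(origin, dtype=np.float64))
    if raster.ndim == origin.size + 1 and raster.shape[-1] == 3:
        n_channels = 3
    elif raster.ndim != origin.size:
        raise ValueError(
            f"raster ndim {raster.ndim} inconsistent with origin dim {origin.size}")
    top = raster.max()
    if top > 1.0:
        raster = raster / top
    if binarize_threshold is not None:
        raster = (raster >= binarize_threshold).astype(np.float64)
    return IntensityField(raster, origin, spacing, n_channels, padding)


# ---------------------------------------------------------------------------
# multilinear sampling

def _prepare(field: IntensityField, points: np.ndarray):
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if not np.all(np.isfinite(pts)):
        raise ValueError("query points must be finite")
    u = (pts - field.origin) / field.spacing
    shape = np.array(field.grid_shape)
    inside = np.all((u >= 0.0) & (u <= shape - 1), axis=1)
    uc = np.clip(u, 0.0, shape - 1)
    i0 = np.minimum(uc.astype(np.int64), shape - 2)
    frac = uc - i0
    return pts, u, inside, i0, frac


def sample(field: IntensityField, points: np.ndarray) -> np.ndarray:
    """Multilinear interpolation; out-of-lattice points get the padding value."""
    return sample_with_gradient(field, points, need_gradient=False)[0]


def sample_with_gradient(field: IntensityField, points: np.ndarray,
                         need_gradient: bool = True):
    """Values and (optionally) physical-coordinate gradients of the field.

    Returns ``(values, gradients)``; for scalar fields values are ``(N,)``
    and gradients ``(N, d)``, for RGB ``(N, 3)`` and ``(N, 3, d)``.
    """
    _, _, inside, i0, frac = _prepare(field, points)
    d = field.ndim
    N = i0.shape[0]
    coeff = field.coefficients
    ch_shape = (3,) if field.n_channels == 3 else ()
    val = np.zeros((N,) + ch_shape)
    grad = np.zeros((N,) + ch_shape + (d,)) if need_gradient else None
    for corner in itertools.product((0, 1), repeat=d):
        idx = tuple(i0[:, a] + corner[a] for a in range(d))
        c = coeff[idx]                                    # (N,) or (N,3)
        w_ax = np.stack([frac[:, a] if corner[a] else 1.0 - frac[:, a]
                         for a in range(d)], axis=1)      # (N, d)
        w = np.prod(w_ax, axis=1)
        val += c * (w[:, None] if ch_shape else w)
        if need_gradient:
            for a in range(d):
                others = np.prod(np.delete(w_ax, a, axis=1), axis=1)
                dw = (1.0 if corner[a] else -1.0) * others / field.spacing[a]
                if ch_shape:
                    grad[:, :, a] += c * dw[:, None]
                else:
                    grad[:, a] += c * dw
    if field.padding == "zero":
        out = ~inside
        val[out] = 0.0
        if need_gradient:
            grad[out] = 0.0
    # "clamp" keeps the clipped-edge interpolation (gradient flattens there)
    return val, grad


# ---------------------------------------------------------------------------
# boundary extraction and distance

def extract_boundary(field: IntensityField, iso_level: float = 0.5,
                     max_points: int = 4096) -> BoundaryCloud:
    """Sample the iso-contour (2-D) or iso-surface (3-D) in physical coords."""
    from skimage import measure

    arr = field.scalar_view()
    lo, hi = arr.min(), arr.max()
    if not (lo < iso_level < hi):
        raise ValueError(
            f"no boundary: field range [{lo:g}, {hi:g}] does not bracket "
            f"iso level {iso_level:g}")
    if field.ndim == 2:
        contours = measure.find_contours(arr, iso_level)
        verts = np.concatenate(contours, axis=0)
    elif field.ndim == 3:
        verts, *_ = measure.marching_cubes(arr, iso_level)
    else:
        raise ValueError("boundary extraction supports 2-D and 3-D fields")
    pts = field.origin + verts * field.spacing
    if pts.shape[0] > max_points:
        stride = int(np.ceil(pts.shape[0] / max_points))
        pts = pts[::stride]
    return BoundaryCloud(pts, iso_level)


def distance(cloud: BoundaryCloud, points: np.ndarray) -> np.ndarray:
    """Exact minimum Euclidean distance from each query to the cloud."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    dist, _ = cloud.tree.query(pts)
    return dist


def smoothed(field: IntensityField, sigma_px: float) -> IntensityField:
    """Gaussian-smoothed copy (sigma in pixels), for optimisation only.

    Widens the capture range of intensity-mismatch gradients on crisp
    binary rasters; overlap metrics should keep scoring the original
    field.
    """
    from scipy.ndimage import gaussian_filter

    if sigma_px <= 0:
        return field
    coeff = field.coefficients
    if field.n_channels == 3:
        coeff = np.stack([gaussian_filter(coeff[..., c], sigma_px)
                          for c in range(3)], axis=-1)
    else:
        coeff = gaussian_filter(coeff, sigma_px)
    return IntensityField(coeff, field.origin, field.spacing,
                          field.n_channels, field.padding)
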