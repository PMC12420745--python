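"""Registration-quality and deformation-field diagnostics.

Dice overlap is evaluated by pulling the source field back to the target
lattice through the inverse map (never forward splatting), thresholding
both at 0.5 for whole-domain scores.  Deformation diagnostics summarise
det F (total / elastic / growth) and principal stretches.
"""

from __future__ import annotations

import numpy as np

from .fields import IntensityField, sample
from .mechanics import GrowthModel

__all__ = ["dice", "lattice_points", "warp_field", "warp_mask",
           "whole_domain_dice", "principal_stretches", "jacobian_summary"]


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|) on same-lattice boolean masks; both empty -> 1."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError("masks must share a lattice")
    denom = A.sum() + B.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(A, B).sum() / denom)


def lattice_points(field: IntensityField) -> np.ndarray:
    """Physical coordinates of every lattice node, flattened to (N, d)."""
    axes = [field.origin[a] + np.arange(n) * field.spacing[a]
            for a, n in enumerate(field.grid_shape)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def warp_field(source: IntensityField, inverse_mapper,
               target_like: IntensityField) -> np.ndarray:
    """Pull-back: value at target node x is source evaluated at inverse(x)."""
    pts = lattice_points(target_like)
    pre = inverse_mapper(pts)
    vals = sample(source, pre)
    shape = target_like.grid_shape
    if source.n_channels == 3:
        shape = shape + (3,)
    return vals.reshape(shape)


def warp_mask(source: IntensityField, inverse_mapper,
              target_like: IntensityField, threshold: float = 0.5) -> np.ndarray:
    arr = warp_field(source, inverse_mapper, target_like)
    if source.n_channels == 3:
        arr = arr.mean(axis=-1)
    return arr >= threshold


def whole_domain_dice(source: IntensityField, target: IntensityField,
                      inverse_mapper, threshold: float = 0.5) -> float:
    """Dice of the warped source against the target over the full lattice."""
    warped = warp_mask(source, inverse_mapper, target, threshold)
    tgt = target.scalar_view() >= threshold
    return dice(warped, tgt)


def principal_stretches(F: np.ndarray) -> np.ndarray:
    """Square roots of eigenvalues of C = F^T F, descending per point.

    Equal to the singular values of F for det F > 0.
    """
    Fb = np.asarray(F, dtype=np.float64)
    single = Fb.ndim == 2
    if single:
        Fb = Fb[None]
    s = np.linalg.svd(Fb, compute_uv=False)
    return s[0] if single else s


def jacobian_summary(F: np.ndarray, growth: GrowthModel | None = None,
                     weights: np.ndarray | None = None,
                     bins: int = 32) -> dict:
    """Masked averages of total/elastic/growth Jacobians plus a histogram.

    ``weights`` (e.g. S1 values at the probe points) weight the averages
    over the body; uniform when omitted.
    """
    Fb = np.asarray(F, dtype=np.float64)
    dets = np.linalg.det(Fb)
    d = Fb.shape[-1]
    if weights is None:
        w = np.ones_like(dets)
    else:
        w = np.asarray(weights, dtype=np.float64)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("jacobian_summary needs positive total weight")
    mean_J = float((w * dets).sum() / wsum)
    det_Fg = 1.0 if growth is None else growth.growth_jacobian(d)
    mean_Je = mean_J / det_Fg
    hist, edges = np.histogram(dets, bins=bins)
    return {
        "mean_det_F": mean_J,
        "mean_det_Fe": mean_Je,
        "det_Fg": det_Fg,
        "min_det_F": float(dets.min()),
        "fraction_nonpositive": float(np.mean(dets <= 0.0)),
        "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
    }
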