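"""Multi-frame registration by composing per-interval predictor/corrector maps.

Given an ordered frame list I_0 ... I_{n_s-1}, each interval j is fitted
with a predictor on the pair (I_{j-1}, I_j) — the approximation that
replaces pulling I_0 back through the accumulated inverse — while the
regularizer and the corrector's potential energy are always evaluated on
the map composed back to frame 0, so the energy bookkeeping never drifts
from the initial configuration.  Growth carries one rate kappa per
interval; the cumulative growth Jacobian is the product over intervals.
The module is agnostic to time direction: frames are just an ordered
list, and a time-reversed analysis simply passes the reversed list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import IntensityField, extract_boundary
from .mechanics import GrowthModel
from .registration import (CorrectorConfig, PredictorConfig, QuadratureSet,
                           RegistrationResult, fit_corrector, fit_predictor)

__all__ = ["SequencePlan", "compose_forward", "compose_backward",
           "fit_sequence"]


def compose_forward(maps, points: np.ndarray) -> np.ndarray:
    """Apply map 1, then 2, ..., then j; the empty list is the identity."""
    x = np.atleast_2d(np.asarray(points))
    for m in maps:
        x = m.forward(x)
    return x


def compose_backward(maps, points: np.ndarray) -> np.ndarray:
    """Inverse recursion of each step applied in reverse order."""
    x = np.atleast_2d(np.asarray(points))
    for m in reversed(maps):
        x = m.inverse(x)
    return x


@dataclass
class SequencePlan:
    """Frames, per-interval fitted results, and sequence-level summaries."""

    frames: list[IntensityField]
    results: list[RegistrationResult] = field(default_factory=list)
    dice_per_step: list[float] = field(default_factory=list)
    kappa_per_step: list[float] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def step_maps(self, upto: int | None = None):
        """Ordered pc maps (corrector o predictor per interval)."""
        out = []
        for r in self.results[:upto]:
            out.append(r.predictor)
            if r.corrector is not None:
                out.append(r.corrector)
        return out

    def forward_map(self, points, upto: int | None = None):
        return compose_forward(self.step_maps(upto), points)

    def backward_map(self, points, upto: int | None = None):
        return compose_backward(self.step_maps(upto), points)

    def cumulative_growth_jacobian(self, dim: int) -> float:
        out = 1.0
        for r in self.results:
            if r.growth is not None:
                out *= r.growth.growth_jacobian(dim)
        return out


def _composed_gradient(results, points: np.ndarray) -> np.ndarray:
    """F of the composed pc map at reference points, chained analytically."""
    x = np.atleast_2d(np.asarray(points, dtype=np.float64))
    d = x.shape[1]
    F = np.broadcast_to(np.eye(d), (x.shape[0], d, d)).copy()
    for r in results:
        maps = [r.predictor] + ([r.corrector] if r.corrector else [])
        for m in maps:
            Fm = m.deformation_gradient(x)
            F = np.einsum("nij,njk->nik", Fm, F)
            x = m.forward(x)
    return F


def fit_sequence(frames: list[IntensityField], quadrature: QuadratureSet,
                 predictor_config: PredictorConfig,
                 corrector_config: CorrectorConfig | None = None,
                 growth: GrowthModel | None = None,
                 kappa_inits: list[float] | None = None,
                 dice_floor: float = 0.0,
                 boundary_max_points: int = 2000) -> SequencePlan:
    """Fit all intervals consecutively; energies refer to frame 0.

    ``kappa_inits`` optionally seeds the growth rate of each interval.
    A predictor Dice below ``dice_floor`` aborts with the step index.
    """
    if len(frames) < 2:
        raise ValueError("a sequence needs at least two frames")
    plan = SequencePlan(frames=list(frames))
    d = quadrature.dim
    flat = quadrature.flat_points()
    n_pts = flat.shape[0]
    from .fields import sample
    s1_0 = sample(frames[0], flat)
    if frames[0].n_channels == 3:
        s1_0 = s1_0.mean(axis=1)
    bnd0 = extract_boundary(frames[0], 0.5, boundary_max_points).points

    # running composed state at the quadrature points and frame-0 boundary;
    # theta_cum is the accumulated growth stretch of previous intervals,
    # divided out of the composed Jacobian so each interval's corrector
    # only absorbs its own growth
    base_pts = flat.copy()
    base_F = np.broadcast_to(np.eye(d), (n_pts, d, d)).copy()
    base_bnd = bnd0.copy()
    theta_cum = 1.0

    for j in range(1, len(frames)):
        pcfg = predictor_config
        pred = fit_predictor(frames[j - 1], frames[j], quadrature, pcfg,
                             _reg_base=(base_pts, base_F, s1_0))
        if pred.dice_predictor is not None and \
                pred.dice_predictor < dice_floor:
            raise RuntimeError(
                f"predictor Dice {pred.dice_predictor:.3f} below floor at "
                f"step {j}")
        result = pred
        if corrector_config is not None:
            ccfg = corrector_config
            g = growth
            if g is not None and kappa_inits is not None:
                from dataclasses import replace
                ccfg = replace(ccfg, kappa_init=kappa_inits[j - 1])
            result = fit_corrector(
                pred, frames[j - 1], frames[j], quadrature, ccfg, growth=g,
                _base=(base_pts, base_F / theta_cum, s1_0, base_bnd))
        plan.results.append(result)
        plan.dice_per_step.append(
            result.dice_corrector if result.dice_corrector is not None
            else result.dice_predictor)
        plan.kappa_per_step.append(
            result.kappa if result.kappa is not None else 0.0)
        if result.growth is not None:
            theta_cum *= result.growth.theta()
        # advance the composed state through this interval's pc map
        step_maps = [result.predictor] + (
            [result.corrector] if result.corrector else [])
        Fstep = np.broadcast_to(np.eye(d), (n_pts, d, d)).copy()
        x = base_pts.astype(np.float64)
        for m in step_maps:
            Fm = m.deformation_gradient(x)
            Fstep = np.einsum("nij,njk->nik", Fm, Fstep)
            x = m.forward(x)
        base_pts = x
        base_F = np.einsum("nij,njk->nik", Fstep, base_F)
        base_bnd = compose_forward(step_maps, base_bnd)
    return plan
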