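"""Desk-scale benchmark pipelines with fixed presets.

Each function generates its synthetic inputs, runs the registration
stages, and returns the measured quantities.  The presets are the
package's reduced-scale study conditions: quadrature around 100
elements per axis (2-D), a few thousand Adam epochs with a learning
rate scaled up in proportion to the reduced epoch count, and mini-batches
of a few hundred elements.  Intensity fields are Gaussian-smoothed by
~1 pixel for optimisation only; every Dice value is scored on the
original crisp rasters.
"""

from __future__ import annotations

import numpy as np

from . import fixtures as fx
from .fields import smoothed
from .mechanics import GrowthModel, Material
from .metrics import jacobian_summary, whole_domain_dice
from .registration import (CorrectorConfig, PredictorConfig, build_quadrature,
                           fit_corrector, fit_predictor)

__all__ = ["plate_extension_benchmark", "shear_contraction_benchmark",
           "growth_recovery_benchmark"]

SMOOTH_PX = 1.2


def plate_extension_benchmark(seed: int = 11, resolution: int = 112,
                              n_cells: int = 48, elements=(100, 56),
                              predictor_epochs: int = 2600,
                              corrector_epochs: int = 900,
                              learning_rate: float = 4e-4,
                              run_corrector: bool = True) -> dict:
    """Plate-with-hole uniaxial extension (StVK, beta = 1/6000).

    The target is the coarse reference Dirichlet solve; returns crisp
    whole-domain Dice for the predictor and (optionally) the gated
    corrector, plus energies and the invertibility report.
    """
    data = fx.plate_hole_extension(resolution=resolution, n_cells=n_cells)
    S1, S2 = data["S1"], data["S2"]
    quad = build_quadrature(data["frame"], elements, 2)
    material = data["material"]
    pcfg = PredictorConfig(
        beta=data["beta"], epochs=predictor_epochs, batch_elements=600,
        learning_rate=learning_rate, seed=seed, material=material,
        regularizer="strain_energy", eval_elements=1000)
    pred = fit_predictor(smoothed(S1, SMOOTH_PX), smoothed(S2, SMOOTH_PX),
                         quad, pcfg)
    pred.dice_predictor = whole_domain_dice(S1, S2, pred.predictor.inverse)
    out = {
        "dice_predictor": pred.dice_predictor,
        "invertibility": pred.invertibility,
        "result": pred,
        "fixture": data,
        "quadrature": quad,
    }
    if run_corrector:
        ccfg = CorrectorConfig(
            epochs=corrector_epochs, batch_elements=400,
            learning_rate=learning_rate, seed=seed + 1, material=material,
            eval_elements=800, boundary_max_points=1200)
        corr = fit_corrector(pred, S1, S2, quad, ccfg)
        out["dice_corrector"] = corr.dice_corrector
        out["energy_predictor"] = corr.energy_predictor
        out["energy_corrector"] = corr.energy_corrector
        out["result"] = corr
    return out


def shear_contraction_benchmark(seed: int = 21, resolution: int = 144,
                                n_cells: int = 48, elements=(108, 90),
                                epochs: int = 3500,
                                learning_rate: float = 4e-4,
                                n_steps: int = 15) -> dict:
    """Neo-Hookean plate under shear with hole contraction; predictor only.

    ``n_steps=1`` degenerates the flow into a plain residual
    displacement network x = X + NN(X), the non-flow baseline that is
    not guaranteed to stay invertible.
    """
    data = fx.plate_hole_shear(resolution=resolution, n_cells=n_cells)
    S1, S2 = data["S1"], data["S2"]
    quad = build_quadrature(data["frame"], elements, 2)
    pcfg = PredictorConfig(
        beta=data["beta"], epochs=epochs, batch_elements=600,
        learning_rate=learning_rate, seed=seed, material=data["material"],
        regularizer="strain_energy", eval_elements=1000, n_steps=n_steps)
    pred = fit_predictor(smoothed(S1, SMOOTH_PX), smoothed(S2, SMOOTH_PX),
                         quad, pcfg)
    dice = whole_domain_dice(S1, S2, pred.predictor.inverse)
    # dense probe of det F over the whole quadrature domain
    report = pred.predictor.invertibility_report(
        quad.flat_points()[::2])
    return {"dice_predictor": dice, "invertibility": report,
            "result": pred, "fixture": data, "quadrature": quad}


def growth_recovery_benchmark(kappa_star: float = 0.05, seed: int = 31,
                              resolution: int = 44, elements=(18, 18, 18),
                              predictor_epochs: int = 900,
                              corrector_epochs: int = 550,
                              learning_rate: float = 8e-4,
                              hidden=(40, 40, 40)) -> dict:
    """Manufactured isotropic-growth ball pair; co-optimise kappa.

    The target is the source ball scaled by exp(kappa*); the corrector
    couples growth so the rate and the residual elastic Jacobian are
    recoverable: kappa ~ kappa*, <det F^e> ~ 1.  The predictor trains on
    occupancy-plus-interior-distance intensities (alignment information
    at the boundary and throughout the body); the gate, energy mask and
    Dice use the binary masks.
    """
    data = fx.ball_growth_pair(kappa=kappa_star, mode="growth",
                               resolution=resolution,
                               raster_mode="occupancy_distance")
    S1, S2 = data["S1"], data["S2"]
    quad = build_quadrature(data["frame"], elements, 2)
    material = Material("neo_hookean")
    pcfg = PredictorConfig(
        beta=1.0 / 6000.0, epochs=predictor_epochs, batch_elements=300,
        learning_rate=learning_rate, seed=seed, material=material,
        eval_elements=300, hidden=hidden)
    pred = fit_predictor(smoothed(data["S1_distance"], 1.0),
                         smoothed(data["S2_distance"], 1.0), quad, pcfg)
    pred.dice_predictor = whole_domain_dice(S1, S2, pred.predictor.inverse)
    growth = GrowthModel(kappa=0.0, mode="growth", t=1.0)
    ccfg = CorrectorConfig(
        epochs=corrector_epochs, batch_elements=150,
        learning_rate=1e-3, seed=seed + 1, material=material,
        eval_elements=250, boundary_max_points=800, kappa_init=0.0,
        hidden=hidden)
    corr = fit_corrector(pred, S1, S2, quad, ccfg, growth=growth)

    # elastic Jacobian averaged over the body with the fitted kappa
    pts = quad.flat_points()
    from .fields import sample
    s1v = sample(S1, pts)
    body = s1v >= 0.5
    probe = pts[body][::max(1, body.sum() // 1500)]
    Fp = pred.predictor.deformation_gradient(probe)
    xq = pred.predictor.forward(probe)
    Fc = corr.corrector.deformation_gradient(xq)
    F = np.einsum("nij,njk->nik", Fc, Fp)
    summary = jacobian_summary(F, growth=corr.growth)
    return {"kappa_star": kappa_star, "kappa_fitted": corr.kappa,
            "mean_det_F": summary["mean_det_F"],
            "mean_det_Fe": summary["mean_det_Fe"],
            "dice_corrector": corr.dice_corrector,
            "result": corr, "fixture": data}
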