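"""Run configuration: schema, YAML loading, validation, and I/O helpers.

A run config collects every knob of a registration run — domain
quadrature, flow steps, predictor/corrector hyperparameters, material
and growth settings — under a single seed, so a run is reproducible from
the file alone.  Numeric defaults mirror the reference setup (Adam lr
5e-5, 15 flow steps, 2 Gauss points per direction, hidden widths 40/60,
mini-batches 4000/2000/1500, mu = lambda = 1 Pa).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fields import IntensityField, build_field
from .mechanics import GrowthModel, Material
from .registration import CorrectorConfig, PredictorConfig

log = logging.getLogger("nodereg")

__all__ = ["RunConfig", "load_config", "setup_logging", "load_image",
           "save_displacement"]


@dataclass
class RunConfig:
    """Validated top-level configuration of a registration run."""

    source: str | None = None
    target: str | None = None
    sequence: list[str] | None = None
    output_dir: str = "nodereg_out"
    domain_bounds: list | None = None        # inferred from images if None
    elements: list | None = None
    gauss: int = 2
    n_steps: int = 15
    seed: int = 0
    beta: float = 1.0 / 6000.0
    epochs_predictor: int = 2000
    epochs_corrector: int = 1500
    batch_predictor: int = 4000
    batch_corrector: int = 2000
    learning_rate: float = 5e-5
    regularizer: str = "strain_energy"
    material: dict = field(default_factory=lambda: {
        "kind": "stvk", "mu": 1.0, "lambda": 1.0})
    growth: dict | None = None               # {mode, kappa_init, t}
    binarize_threshold: float | None = 0.5
    skip_corrector: bool = False
    dice_floor: float = 0.0

    def validate(self) -> None:
        errors = []
        if self.sequence is None and (self.source is None
                                      or self.target is None):
            errors.append("source/target (or sequence) paths are required")
        if self.beta < 0:
            errors.append("beta must be nonnegative")
        if self.gauss < 1:
            errors.append("gauss must be >= 1")
        if self.n_steps < 1:
            errors.append("n_steps must be >= 1")
        if self.epochs_predictor < 1 or self.epochs_corrector < 1:
            errors.append("epoch counts must be >= 1")
        kind = self.material.get("kind", "stvk")
        if kind not in ("stvk", "neo_hookean", "ablation_poly"):
            errors.append(f"material.kind {kind!r} unknown")
        if self.material.get("mu", 1.0) <= 0:
            errors.append("material.mu must be positive")
        if self.growth is not None and \
                self.growth.get("mode") not in ("growth", "shrinkage"):
            errors.append("growth.mode must be 'growth' or 'shrinkage'")
        if self.regularizer not in ("strain_energy", "fnorm_logJ"):
            errors.append(f"regularizer {self.regularizer!r} unknown")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    # -- derived objects ---------------------------------------------

    def material_obj(self) -> Material:
        return Material(self.material.get("kind", "stvk"),
                        lam=self.material.get("lambda", 1.0),
                        mu=self.material.get("mu", 1.0))

    def growth_obj(self) -> GrowthModel | None:
        if self.growth is None:
            return None
        return GrowthModel(kappa=self.growth.get("kappa_init", 0.0),
                           mode=self.growth["mode"],
                           t=self.growth.get("t", 1.0))

    def predictor_config(self) -> PredictorConfig:
        return PredictorConfig(
            beta=self.beta, epochs=self.epochs_predictor,
            batch_elements=self.batch_predictor,
            learning_rate=self.learning_rate, seed=self.seed,
            regularizer=self.regularizer, material=self.material_obj(),
            n_steps=self.n_steps)

    def corrector_config(self) -> CorrectorConfig:
        kappa0 = 0.0 if self.growth is None \
            else self.growth.get("kappa_init", 0.0)
        return CorrectorConfig(
            epochs=self.epochs_corrector,
            batch_elements=self.batch_corrector,
            learning_rate=self.learning_rate, seed=self.seed + 1,
            material=self.material_obj(), n_steps=self.n_steps,
            kappa_init=kappa0)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ValueError(f"invalid config: unknown keys {unknown}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def setup_logging(output_dir: str | None = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if output_dir is not None:
        Path(output_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(output_dir) / "run.log"))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# image I/O: PNG / plain arrays for 2-D, NIfTI for 3-D

def load_image(path, binarize_threshold: float | None = 0.5,
               default_bounds=(-1.0, 1.0)) -> IntensityField:
    """Read PNG (gray or RGB), .npy arrays, or NIfTI volumes as fields.

    PNGs get axis order transposed so array axis 0 is physical x.  With
    no physical metadata (PNG/npy) the lattice spans ``default_bounds``
    per axis; NIfTI affines supply origin/spacing (diagonal affines
    only — oblique orientations are out of scope).
    """
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
        origin, spacing = _default_geometry(arr.shape, default_bounds)
        return build_field(arr, origin, spacing, binarize_threshold)
    if path.suffix in (".png", ".bmp", ".tif", ".tiff"):
        from PIL import Image
        img = np.asarray(Image.open(path))
        if img.ndim == 3:
            img = img[..., :3]
            arr = np.transpose(img, (1, 0, 2))[:, ::-1]
        else:
            arr = img.T[:, ::-1]
        origin, spacing = _default_geometry(arr.shape[:2], default_bounds)
        return build_field(arr, origin, spacing, binarize_threshold)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        aff = img.affine
        if np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))).max() > 1e-6:
            raise ValueError("oblique NIfTI affines are not supported")
        spacing = np.diag(aff[:3, :3])
        origin = aff[:3, 3].astype(float)
        # normalise negative spacings by flipping axes
        for a in range(3):
            if spacing[a] < 0:
                arr = np.flip(arr, axis=a)
                origin[a] = origin[a] + spacing[a] * (arr.shape[a] - 1)
                spacing[a] = -spacing[a]
        return build_field(arr, origin, spacing, binarize_threshold)
    raise ValueError(f"unsupported image format: {path}")


def _default_geometry(shape, bounds):
    lo, hi = bounds
    shape = np.array(shape)
    spacing = (hi - lo) / (shape - 1)
    origin = np.full(len(shape), lo, dtype=float)
    return origin, spacing


def save_displacement(path, disp: np.ndarray, field_like: IntensityField
                      ) -> None:
    """Write the displacement lattice (2-D: .npy, 3-D: NIfTI with affine)."""
    path = Path(path)
    if field_like.ndim == 3:
        import nibabel as nib
        aff = np.eye(4)
        aff[:3, :3] = np.diag(field_like.spacing)
        aff[:3, 3] = field_like.origin
        nib.save(nib.Nifti1Image(disp.astype(np.float32), aff), str(path))
    else:
        np.save(path.with_suffix(".npy"), disp)
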