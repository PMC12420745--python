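"""Kinematics, hyperelastic strain-energy densities, and growth kinematics.

Three potentials are available: Saint Venant-Kirchhoff, neo-Hookean, and
a fixed-coefficient polynomial in the invariants used for ablation
studies.  All depend on F only through C = F^T F (frame indifference)
and vanish at F = I.  Volumetric growth follows the multiplicative
split F = F^e F^g with isotropic F^g = theta I, theta(t) = exp(+-kappa t);
only the elastic part F^e = F / theta stores energy.

Functions accept a single (d, d) matrix or an (N, d, d) batch and return
correspondingly shaped results.  Derivative helpers return dpsi/dF,
which is all the energy-minimisation loops need (stress tensors are
never assembled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Material", "GrowthModel", "kinematics", "psi", "dpsi_dF",
           "regularizer", "dreg_dF", "elastic_part"]

_KINDS = ("stvk", "neo_hookean", "ablation_poly")


@dataclass(frozen=True)
class Material:
    """Strain-energy selection with Lame parameters (Pa); defaults 1 Pa.

    ``ablation_poly`` ignores ``lam``/``mu`` (its coefficients are fixed).
    ``stvk_literal_trace`` switches the StVK volumetric term from the
    classical (lambda/2)(tr E)^2 to a literal (lambda/2)(tr E).
    """

    kind: str = "stvk"
    lam: float = 1.0
    mu: float = 1.0
    stvk_literal_trace: bool = False

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.mu <= 0:
            raise ValueError("shear modulus mu must be positive")


@dataclass(frozen=True)
class GrowthModel:
    """Isotropic exponential growth state theta(t) = exp(+-kappa t).

    ``mode`` is "growth" (+kappa) or "shrinkage" (-kappa); ``t`` defaults
    to one pseudo-time unit per registered frame interval.
    """

    kappa: float = 0.0
    mode: str = "growth"
    t: float = 1.0

    def __post_init__(self):
        if self.mode not in ("growth", "shrinkage"):
            raise ValueError("growth mode must be 'growth' or 'shrinkage'")

    @property
    def sign(self) -> float:
        return 1.0 if self.mode == "growth" else -1.0

    def theta(self, kappa: float | None = None) -> float:
        k = self.kappa if kappa is None else kappa
        return float(np.exp(self.sign * k * self.t))

    def growth_jacobian(self, dim: int, kappa: float | None = None) -> float:
        """det F^g = theta^dim."""
        return self.theta(kappa) ** dim


# ---------------------------------------------------------------------------
# kinematic measures

def _batched(F: np.ndarray):
    F = np.asarray(F, dtype=np.float64)
    single = F.ndim == 2
    return (F[None] if single else F), single


def kinematics(F: np.ndarray) -> dict:
    """C = F^T F, Green strain E, invariants I1, I2 and J = det F."""
    Fb, single = _batched(F)
    C = np.einsum("nji,njk->nik", Fb, Fb)
    d = Fb.shape[-1]
    E = 0.5 * (C - np.eye(d))
    I1 = np.trace(C, axis1=1, axis2=2)
    trC2 = np.einsum("nij,nji->n", C, C)
    I2 = 0.5 * (I1 ** 2 - trC2)
    J = np.linalg.det(Fb)
    out = {"C": C, "E": E, "I1": I1, "I2": I2, "J": J}
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def _inv_T(F: np.ndarray) -> np.ndarray:
    return np.swapaxes(np.linalg.inv(F), -1, -2)


# ---------------------------------------------------------------------------
# strain-energy densities and their F-derivatives

def _psi_impl(material: Material, Fb: np.ndarray, need_grad: bool):
    d = Fb.shape[-1]
    C = np.einsum("nji,njk->nik", Fb, Fb)
    I = np.eye(d)
    if material.kind == "stvk":
        lam, mu = material.lam, material.mu
        E = 0.5 * (C - I)
        trE = np.trace(E, axis1=1, axis2=2)
        trE2 = np.einsum("nij,nji->n", E, E)
        if material.stvk_literal_trace:
            val = 0.5 * lam * trE + mu * trE2
            S = 0.5 * lam * I + 2.0 * mu * E
        else:
            val = 0.5 * lam * trE ** 2 + mu * trE2
            S = lam * trE[:, None, None] * I + 2.0 * mu * E
        grad = np.einsum("nij,njk->nik", Fb, S) if need_grad else None
        return val, grad
    if material.kind == "neo_hookean":
        lam, mu = material.lam, material.mu
        J = np.linalg.det(Fb)
        if np.any(J <= 0):
            raise ValueError("non-invertible state: det F <= 0 in neo-Hookean psi")
        logJ = np.log(J)
        trC = np.trace(C, axis1=1, axis2=2)
        val = 0.5 * mu * (trC - d) - mu * logJ + 0.5 * lam * logJ ** 2
        grad = None
        if need_grad:
            FiT = _inv_T(Fb)
            grad = mu * Fb + (lam * logJ - mu)[:, None, None] * FiT
        return val, grad
    # ablation polynomial; 2-D states are embedded as plane deformations
    J = np.linalg.det(Fb)
    trC = np.trace(C, axis1=1, axis2=2)
    trC2 = np.einsum("nij,nji->n", C, C)
    pad = 3 - d                       # embedded identity directions
    I1 = trC + pad
    I2 = 0.5 * (I1 ** 2 - (trC2 + pad))
    val = (3.0 * (J - 1.0) ** 2 + (I1 - 3.0) + (I2 - 3.0) / 12.0
           + (I1 - 3.0) ** 2)
    grad = None
    if need_grad:
        FiT = _inv_T(Fb)
        FC = np.einsum("nij,njk->nik", Fb, C)
        dJ = J[:, None, None] * FiT
        dI1 = 2.0 * Fb
        dI2 = I1[:, None, None] * 2.0 * Fb - 2.0 * FC
        grad = (6.0 * (J - 1.0)[:, None, None] * dJ + dI1 + dI2 / 12.0
                + 2.0 * (I1 - 3.0)[:, None, None] * dI1)
    return val, grad


def psi(material: Material, F: np.ndarray) -> np.ndarray | float:
    """Strain energy density (Pa); zero at F = I for every kind."""
    Fb, single = _batched(F)
    val, _ = _psi_impl(material, Fb, need_grad=False)
    return float(val[0]) if single else val


def dpsi_dF(material: Material, F: np.ndarray):
    """(psi, dpsi/dF) evaluated together; shapes follow the input."""
    Fb, single = _batched(F)
    val, grad = _psi_impl(material, Fb, need_grad=True)
    if single:
        return float(val[0]), grad[0]
    return val, grad


# ---------------------------------------------------------------------------
# regularizers

def regularizer(kind: str, material: Material, F: np.ndarray):
    """R(F): 'strain_energy' delegates to psi; 'fnorm_logJ' is ||F||^2 + (log J)^2."""
    return _reg_impl(kind, material, F, need_grad=False)[0]


def dreg_dF(kind: str, material: Material, F: np.ndarray):
    return _reg_impl(kind, material, F, need_grad=True)


def _reg_impl(kind: str, material: Material, F: np.ndarray, need_grad: bool):
    Fb, single = _batched(F)
    if kind == "strain_energy":
        val, grad = _psi_impl(material, Fb, need_grad)
    elif kind == "fnorm_logJ":
        J = np.linalg.det(Fb)
        if np.any(J <= 0):
            raise ValueError("det F <= 0: log-determinant regularizer undefined")
        logJ = np.log(J)
        val = np.einsum("nij,nij->n", Fb, Fb) + logJ ** 2
        grad = None
        if need_grad:
            grad = 2.0 * Fb + 2.0 * logJ[:, None, None] * _inv_T(Fb)
    else:
        raise ValueError(f"unknown regularizer kind {kind!r}")
    if single:
        return float(val[0]), (grad[0] if need_grad else None)
    return val, grad


# ---------------------------------------------------------------------------
# growth split

def elastic_part(F: np.ndarray, growth: GrowthModel,
                 kappa: float | None = None) -> np.ndarray:
    """F^e = F / theta for isotropic F^g = theta I (commutes with F)."""
    theta = growth.theta(kappa)
    return np.asarray(F, dtype=np.float64) / theta
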