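"""Neural-ODE flow maps: forward-Euler transport, inverses, gradients.

The transformation x(X) is the flow of dx/dt = NN(x) integrated with
``n_steps`` explicit Euler steps over unit pseudo-time.  With the output
layer of NN initialised to zero the map starts as the exact identity,
and for small enough steps every residual update is contractive, which
keeps the composed map injective (monitored via det F rather than
proved).  A distance gate multiplies each velocity increment by the
distance to a boundary point cloud, so gated flows leave those boundary
points exactly fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import VelocityNetwork
from .fields import BoundaryCloud

__all__ = ["FlowConfig", "DistanceGate", "FlowMap", "FlowTape",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class FlowConfig:
    """Step count of the Euler discretisation; dt = 1/n_steps exactly."""

    n_steps: int = 15

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be a positive integer")

    @property
    def dt(self) -> float:
        return 1.0 / self.n_steps


class DistanceGate:
    """D_p(x): minimum distance to the predictor's transported boundary.

    Multiplies the corrector velocity so the transported boundary cannot
    move.  The gate is re-evaluated at each step position; when
    differentiating training losses its value is treated as a constant
    (subgradient zero at the cloud), while the exact map derivative in
    :meth:`FlowMap.deformation_gradient` includes the a.e. gradient
    (x - nearest)/D.
    """

    def __init__(self, cloud: BoundaryCloud):
        self.cloud = cloud

    def __call__(self, points: np.ndarray) -> np.ndarray:
        d, _ = self.cloud.tree.query(points)
        return d

    def value_and_direction(self, points: np.ndarray):
        d, idx = self.cloud.tree.query(points)
        diff = points - self.cloud.points[idx]
        safe = np.where(d > 0, d, 1.0)
        return d, diff / safe[:, None]


class FlowTape:
    """Per-step record of a forward transport, for reverse accumulation."""

    __slots__ = ("positions", "caches", "gates", "dt")

    def __init__(self, positions, caches, gates, dt):
        self.positions = positions   # [x_0, ..., x_n]
        self.caches = caches         # network activation cache per step
        self.gates = gates           # gate values per step (or None)
        self.dt = dt


class FlowMap:
    """Velocity network + step count (+ optional distance gate)."""

    def __init__(self, network: VelocityNetwork,
                 config: FlowConfig | None = None,
                 gate: DistanceGate | None = None):
        self.network = network
        self.config = config or FlowConfig()
        self.gate = gate

    @property
    def dim(self) -> int:
        return self.network.dim

    # -- transport ----------------------------------------------------

    def _check(self, x: np.ndarray, step: int) -> None:
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite flow state at Euler step {step}")

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Transport an (N, d) batch through all Euler steps."""
        x = np.atleast_2d(np.asarray(points))
        if x.shape[1] != self.dim:
            raise ValueError(f"points have dim {x.shape[1]}, network {self.dim}")
        self._check(x, 0)
        dt = self.config.dt
        for i in range(self.config.n_steps):
            v = self.network.forward(x)
            if self.gate is not None:
                v = v * self.gate(x)[:, None]
            x = x + dt * v
            self._check(x, i + 1)
        return x

    def forward_tape(self, points: np.ndarray) -> tuple[np.ndarray, FlowTape]:
        """Forward transport recording activations for :meth:`backward_tape`."""
        x = np.atleast_2d(np.asarray(points))
        self._check(x, 0)
        dt = self.config.dt
        positions, caches, gates = [x], [], []
        for i in range(self.config.n_steps):
            cache: list = []
            v = self.network.forward(x, cache)
            g = None
            if self.gate is not None:
                g = self.gate(x).astype(x.dtype)
                v = v * g[:, None]
            x = x + dt * v
            self._check(x, i + 1)
            positions.append(x)
            caches.append(cache)
            gates.append(g)
        return x, FlowTape(positions, caches, gates, dt)

    def backward_tape(self, tape: FlowTape, gbar: np.ndarray,
                      param_grads: list[np.ndarray]) -> np.ndarray:
        """Reverse accumulation of d(loss)/d(params) given d(loss)/d(x_n).

        Gate values are constants here (see :class:`DistanceGate`).
        ``param_grads`` (flat array list matching ``network.flat_arrays``)
        is accumulated in place; returns d(loss)/d(x_0).
        """
        dt = tape.dt
        for i in range(len(tape.caches) - 1, -1, -1):
            g = tape.gates[i]
            up = gbar * dt if g is None else gbar * (dt * g[:, None])
            gx, grads = self.network.vjp(tape.caches[i], up)
            k = 0
            for gW, gb in grads:
                param_grads[k] += gW
                param_grads[k + 1] += gb
                k += 2
            gbar = gbar + gx
        return gbar

    def inverse(self, points: np.ndarray, newton_polish: int = 0) -> np.ndarray:
        """Reverse-Euler recursion approximating the inverse map.

        ``newton_polish`` optional fixed-point sweeps refine each output
        so that forward(inverse(x)) is closer to x.
        """
        x = np.atleast_2d(np.asarray(points))
        self._check(x, 0)
        dt = self.config.dt
        for i in range(self.config.n_steps):
            v = self.network.forward(x)
            if self.gate is not None:
                v = v * self.gate(x)[:, None]
            x = x - dt * v
            self._check(x, i + 1)
        for _ in range(newton_polish):
            F = self.deformation_gradient(x)
            r = self.forward(x) - np.atleast_2d(np.asarray(points))
            x = x - np.linalg.solve(F, r[:, :, None])[:, :, 0]
        return x

    # -- derivatives --------------------------------------------------

    def deformation_gradient(self, points: np.ndarray) -> np.ndarray:
        """Exact F = dx/dX of the discrete composed map, (N, d, d).

        Differentiates every Euler step, including the gate factor via
        its a.e. gradient; at gate-zero points the subgradient is zero.
        """
        x = np.atleast_2d(np.asarray(points, dtype=np.float64))
        self._check(x, 0)
        N, d = x.shape
        dt = self.config.dt
        F = np.broadcast_to(np.eye(d), (N, d, d)).copy()
        net = self.network if self.network.params[0][0].dtype == np.float64 \
            else self.network.astype(np.float64)
        for i in range(self.config.n_steps):
            cache: list = []
            v = net.forward(x, cache)
            A = net.input_jacobian(cache)          # dNN_i/dx_j
            if self.gate is not None:
                gval, gdir = self.gate.value_and_direction(x)
                step_jac = (gval[:, None, None] * A
                            + v[:, :, None] * gdir[:, None, :])
                v = v * gval[:, None]
            else:
                step_jac = A
            F = F + dt * np.einsum("nij,njk->nik", step_jac, F)
            x = x + dt * v
            self._check(x, i + 1)
        return F

    def invertibility_report(self, probe_points: np.ndarray) -> dict:
        """Summary of det F over probe points; flags J <= 0 violations."""
        F = self.deformation_gradient(probe_points)
        dets = np.linalg.det(F)
        return {
            "min_det": float(dets.min()),
            "max_det": float(dets.max()),
            "mean_det": float(dets.mean()),
            "fraction_nonpositive": float(np.mean(dets <= 0.0)),
            "n_probes": int(dets.size),
        }


# ---------------------------------------------------------------------------
# checkpoints (portable .npz containers)

def save_checkpoint(path, flow: FlowMap, extra: dict | None = None) -> None:
    arrays = {"n_steps": np.array(flow.config.n_steps),
              "n_layers": np.array(len(flow.network.params)),
              "activation": np.array(flow.network.activation)}
    for i, (W, b) in enumerate(flow.network.params):
        arrays[f"W{i}"] = np.asarray(W, dtype=np.float64)
        arrays[f"b{i}"] = np.asarray(b, dtype=np.float64)
    if flow.gate is not None:
        arrays["gate_points"] = flow.gate.cloud.points
        arrays["gate_level"] = np.array(flow.gate.cloud.source_level)
    for k, v in (extra or {}).items():
        arrays[f"x_{k}"] = np.asarray(v)
    np.savez(path, **arrays)


def load_checkpoint(path) -> FlowMap:
    with np.load(path) as z:
        n_layers = int(z["n_layers"])
        params = [(z[f"W{i}"], z[f"b{i}"]) for i in range(n_layers)]
        gate = None
        if "gate_points" in z:
            gate = DistanceGate(
                BoundaryCloud(z["gate_points"], float(z["gate_level"])))
        act = str(z["activation"]) if "activation" in z else "tanh"
        return FlowMap(VelocityNetwork(params, act),
                       FlowConfig(int(z["n_steps"])), gate)
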