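"""Synthetic benchmark generation with known ground truth.

Everything the test-suite and the acceptance runs register is generated
here: multiply-connected plates on [-1, 1]^2 whose targets come from a
coarse Dirichlet hyperelastic solve (the reference-deformation oracle),
and pairs produced by manufactured diffeomorphisms with exact inverses
and gradients (translations, rotations, affine stretches, radial
inflation, isotropic exponential growth).  3-D pairs are balls deformed
by exact growth/shrinkage maps.

The reference solver is a structured-grid bilinear-element energy
minimisation — deliberately coarse, it exists to produce target rasters
and to be checked against closed-form homogeneous solutions, not to be
a production finite-element package.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage, optimize

from .fields import IntensityField, build_field
from .mechanics import Material, _psi_impl

__all__ = ["ShapeSpec", "ManufacturedMap", "rasterize", "make_pair",
           "make_labels", "make_bvp_target", "translation", "rotation",
           "affine_stretch", "radial_inflation", "isotropic_growth",
           "plate_hole_extension", "plate_hole_shear",
           "plate_3holes_bending", "disc_translation", "ball_growth_pair",
           "FIXTURES"]


# ---------------------------------------------------------------------------
# shapes

@dataclass
class ShapeSpec:
    """Solid body = outer region minus elliptical holes.

    ``body`` is either ("box", bounds) or ("ellipsoid", center, semiaxes);
    holes are dicts with center, semiaxes and (2-D only) rotation.
    """

    body: tuple
    holes: list[dict] = dfield(default_factory=list)

    @property
    def dim(self) -> int:
        if self.body[0] == "box":
            return len(self.body[1])
        return len(self.body[1])

    def body_bounds(self) -> list[tuple[float, float]]:
        if self.body[0] == "box":
            return [tuple(b) for b in self.body[1]]
        c, s = np.asarray(self.body[1]), np.asarray(self.body[2])
        return [(float(ci - si), float(ci + si)) for ci, si in zip(c, s)]

    def inside(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.body[0] == "box":
            lo = np.array([b[0] for b in self.body[1]])
            hi = np.array([b[1] for b in self.body[1]])
            ok = np.all((X >= lo) & (X <= hi), axis=1)
        else:
            c = np.asarray(self.body[1])
            s = np.asarray(self.body[2])
            ok = (((X - c) / s) ** 2).sum(axis=1) <= 1.0
        for h in self.holes:
            ok &= ~self._in_hole(h, X)
        return ok

    @staticmethod
    def _in_hole(h: dict, X: np.ndarray) -> np.ndarray:
        c = np.asarray(h["center"], dtype=float)
        s = np.asarray(h["semiaxes"], dtype=float)
        u = X - c
        rot = h.get("rotation", 0.0)
        if rot and u.shape[1] == 2:
            ca, sa = np.cos(rot), np.sin(rot)
            u = u @ np.array([[ca, sa], [-sa, ca]]).T
        return ((u / s) ** 2).sum(axis=1) <= 1.0

    @staticmethod
    def plate_with_hole(radius: float = 0.5) -> "ShapeSpec":
        return ShapeSpec(("box", [(-1.0, 1.0), (-1.0, 1.0)]),
                         [{"center": (0.0, 0.0), "semiaxes": (radius, radius)}])

    @staticmethod
    def disc(radius: float = 0.5, center=(0.0, 0.0)) -> "ShapeSpec":
        return ShapeSpec(("ellipsoid", center, (radius, radius)))

    @staticmethod
    def ball(radius: float = 0.55, center=(0.0, 0.0, 0.0)) -> "ShapeSpec":
        return ShapeSpec(("ellipsoid", center, (radius,) * 3))


def _frame_lattice(frame, resolution):
    frame = [(float(a), float(b)) for a, b in frame]
    d = len(frame)
    if np.isscalar(resolution):
        resolution = (int(resolution),) * d
    axes = [np.linspace(lo, hi, n) for (lo, hi), n in zip(frame, resolution)]
    spacing = np.array([ax[1] - ax[0] for ax in axes])
    origin = np.array([ax[0] for ax in axes])
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    return pts, origin, spacing, tuple(len(ax) for ax in axes)


def _distance_rgb(mask: np.ndarray, spacing, occupancy: bool = False
                  ) -> np.ndarray:
    """Interior-distance-coded RGB raster (zero outside the body).

    All channels grade monotonically with interior depth and vanish on
    the boundary; with ``occupancy`` the first channel is replaced by
    the occupancy step itself, adding explicit boundary information.
    """
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    top = dist.max()
    dn = dist / top if top > 0 else dist
    first = mask.astype(float) if occupancy else dn
    rgb = np.stack([first, dn ** 2, np.sqrt(dn)], axis=-1)
    return rgb * mask[..., None]


def rasterize(shape: ShapeSpec, mode: str = "binary", resolution: int = 128,
              frame=None, inside_fn=None) -> IntensityField:
    """Occupancy (or interior-distance RGB) raster of a shape.

    ``frame`` defaults to the body bounds padded by 10%; ``inside_fn``
    overrides the membership test (used for deformed configurations).
    """
    if frame is None:
        frame = [(lo - 0.1 * (hi - lo), hi + 0.1 * (hi - lo))
                 for lo, hi in shape.body_bounds()]
    pts, origin, spacing, grid = _frame_lattice(frame, resolution)
    inside = (inside_fn or shape.inside)(pts).reshape(grid)
    if mode == "binary":
        return build_field(inside.astype(float), origin, spacing,
                           binarize_threshold=0.5)
    if mode == "distance":
        dist = ndimage.distance_transform_edt(inside, sampling=spacing)
        top = dist.max()
        return build_field(dist / top if top > 0 else dist, origin, spacing)
    if mode == "distance_rgb":
        return build_field(_distance_rgb(inside, spacing), origin, spacing)
    if mode == "occupancy_distance":
        return build_field(_distance_rgb(inside, spacing, occupancy=True),
                           origin, spacing)
    raise ValueError(f"unknown raster mode {mode!r}")


# ---------------------------------------------------------------------------
# manufactured diffeomorphisms

@dataclass
class ManufacturedMap:
    """Closed-form diffeomorphism with exact inverse and gradient."""

    name: str
    map: callable
    inverse: callable
    grad: callable

    def __call__(self, X):
        return self.map(np.atleast_2d(np.asarray(X, dtype=np.float64)))


def translation(v) -> ManufacturedMap:
    v = np.asarray(v, dtype=np.float64)

    def grad(X):
        X = np.atleast_2d(X)
        return np.broadcast_to(np.eye(v.size), (X.shape[0],) + (v.size,) * 2)

    return ManufacturedMap("translation", lambda X: X + v, lambda x: x - v,
                           grad)


def affine_stretch(A, center=None) -> ManufacturedMap:
    """x = c + A (X - c); covers uniform/anisotropic stretches and shears."""
    A = np.asarray(A, dtype=np.float64)
    d = A.shape[0]
    c = np.zeros(d) if center is None else np.asarray(center, dtype=np.float64)
    Ai = np.linalg.inv(A)

    def grad(X):
        X = np.atleast_2d(X)
        return np.broadcast_to(A, (X.shape[0], d, d))

    return ManufacturedMap("affine",
                           lambda X: c + (X - c) @ A.T,
                           lambda x: c + (x - c) @ Ai.T, grad)


def rotation(angle: float, center=(0.0, 0.0)) -> ManufacturedMap:
    ca, sa = np.cos(angle), np.sin(angle)
    return affine_stretch(np.array([[ca, -sa], [sa, ca]]), center)


def isotropic_growth(kappa: float, dim: int, t: float = 1.0,
                     mode: str = "growth", center=None) -> ManufacturedMap:
    """Uniform scaling by theta = exp(+-kappa t) about a center."""
    sign = 1.0 if mode == "growth" else -1.0
    theta = float(np.exp(sign * kappa * t))
    m = affine_stretch(theta * np.eye(dim), center)
    m.name = f"isotropic_{mode}"
    return m


def radial_inflation(amplitude: float, width: float = 0.5,
                     center=(0.0, 0.0)) -> ManufacturedMap:
    """x = c + g(r) u with g = 1 + a exp(-r^2 / (2 w^2)), u = X - c.

    Diffeomorphic for moderate amplitudes (monotone radial profile);
    inverse via per-point Newton on the scalar radius to 1e-13.
    """
    a, w = float(amplitude), float(width)
    c = np.asarray(center, dtype=np.float64)

    def g_of(r):
        return 1.0 + a * np.exp(-r ** 2 / (2 * w ** 2))

    def fwd(X):
        u = X - c
        r = np.linalg.norm(u, axis=1)
        return c + g_of(r)[:, None] * u

    def grad(X):
        X = np.atleast_2d(X)
        u = X - c
        r = np.linalg.norm(u, axis=1)
        d = u.shape[1]
        g = g_of(r)
        gp = a * np.exp(-r ** 2 / (2 * w ** 2)) * (-r / w ** 2)
        safe = np.where(r > 0, r, 1.0)
        uhat = u / safe[:, None]
        out = g[:, None, None] * np.broadcast_to(
            np.eye(d), (len(r), d, d)).copy()
        out += gp[:, None, None] * np.einsum("ni,nj->nij", uhat, u)
        return out

    def inv(x):
        x = np.atleast_2d(x)
        u = x - c
        s = np.linalg.norm(u, axis=1)
        R = s.copy()
        for _ in range(60):
            f = R * g_of(R) - s
            df = g_of(R) + R * a * np.exp(-R ** 2 / (2 * w ** 2)) * (-R / w ** 2)
            step = f / df
            R = R - step
            if np.all(np.abs(step) < 1e-13):
                break
        safe = np.where(s > 0, s, 1.0)
        return c + (R / safe)[:, None] * u

    return ManufacturedMap("radial_inflation", fwd, inv, grad)


def bending(curvature: float, neutral_radius: float | None = None
            ) -> ManufacturedMap:
    """Plane beam bending: straight fibres X1 wrap onto arcs of radius
    R0 - X2 about (0, R0), R0 = 1/curvature.  Exact inverse and gradient."""
    R0 = 1.0 / curvature if neutral_radius is None else neutral_radius

    def fwd(X):
        phi = X[:, 0] / R0
        rad = R0 - X[:, 1]
        return np.stack([rad * np.sin(phi), R0 - rad * np.cos(phi)], axis=1)

    def inv(x):
        dx, dy = x[:, 0], R0 - x[:, 1]
        rad = np.hypot(dx, dy)
        phi = np.arctan2(dx, dy)
        return np.stack([R0 * phi, R0 - rad], axis=1)

    def grad(X):
        X = np.atleast_2d(X)
        phi = X[:, 0] / R0
        rad = R0 - X[:, 1]
        c, s = np.cos(phi), np.sin(phi)
        F = np.empty((X.shape[0], 2, 2))
        F[:, 0, 0] = rad * c / R0
        F[:, 0, 1] = -s
        F[:, 1, 0] = rad * s / R0
        F[:, 1, 1] = c
        return F

    return ManufacturedMap("bending", fwd, inv, grad)


def make_pair(shape: ShapeSpec, mmap: ManufacturedMap, mode: str = "binary",
              resolution: int = 128, frame=None) -> dict:
    """Source/target rasters of a shape pushed through a manufactured map.

    The target membership test is exact: pixel x is inside the deformed
    body iff inverse(x) is inside the shape.  Ground-truth displacement
    and Jacobian-determinant lattices ride along.
    """
    if frame is None:
        bb = shape.body_bounds()
        # frame covering source and deformed body with margin
        corners, origin, spacing, grid = None, None, None, None
        lo = np.array([b[0] for b in bb])
        hi = np.array([b[1] for b in bb])
        probe = np.array(np.meshgrid(*[np.linspace(l, h, 9)
                                       for l, h in bb], indexing="ij"))
        probe = probe.reshape(len(bb), -1).T
        mapped = mmap(probe)
        lo = np.minimum(lo, mapped.min(axis=0))
        hi = np.maximum(hi, mapped.max(axis=0))
        pad = 0.12 * (hi - lo)
        frame = list(zip(lo - pad, hi + pad))
    S1 = rasterize(shape, mode, resolution, frame)
    S2 = rasterize(shape, mode, resolution, frame,
                   inside_fn=lambda x: shape.inside(mmap.inverse(x)))
    pts, origin, spacing, grid = _frame_lattice(frame, resolution)
    disp = (mmap(pts) - pts).reshape(grid + (len(grid),))
    detF = np.linalg.det(mmap.grad(pts)).reshape(grid)
    return {"S1": S1, "S2": S2, "map": mmap, "frame": frame,
            "displacement": disp, "detF": detF}


def make_labels(shape: ShapeSpec, mmap: ManufacturedMap, n_labels: int = 4,
                resolution: int = 128, frame=None) -> list[dict]:
    """Angular-sector label partition of the body, deformed consistently."""
    pair = make_pair(shape, mmap, "binary", resolution, frame)
    S1, S2 = pair["S1"], pair["S2"]
    pts, origin, spacing, grid = _frame_lattice(pair["frame"], resolution)
    if shape.body[0] == "ellipsoid":
        c = np.asarray(shape.body[1], dtype=float)
    else:
        bb = shape.body_bounds()
        c = np.array([(lo + hi) / 2 for lo, hi in bb])

    def sector(P):
        ang = np.arctan2(P[:, 1] - c[1], P[:, 0] - c[0]) % (2 * np.pi)
        return np.floor(ang / (2 * np.pi / n_labels)).astype(int)

    src_in = shape.inside(pts)
    src_lab = sector(pts)
    pre = mmap.inverse(pts)
    tgt_in = shape.inside(pre)
    tgt_lab = sector(pre)
    out = []
    for k in range(n_labels):
        out.append({
            "label": k,
            "source": (src_in & (src_lab == k)).reshape(grid),
            "target": (tgt_in & (tgt_lab == k)).reshape(grid),
        })
    return out


# ---------------------------------------------------------------------------
# coarse reference Dirichlet solve (structured bilinear elements)

class _StructuredSolver:
    """Energy-minimising displacement solve on a uniform quad grid."""

    def __init__(self, shape: ShapeSpec, n_cells: int = 48,
                 material: Material | None = None):
        self.shape = shape
        self.material = material or Material("stvk")
        bb = shape.body_bounds()
        (x0, x1), (y0, y1) = bb
        self.nx = self.ny = n_cells
        xs = np.linspace(x0, x1, n_cells + 1)
        ys = np.linspace(y0, y1, n_cells + 1)
        self.hx, self.hy = xs[1] - xs[0], ys[1] - ys[0]
        XX, YY = np.meshgrid(xs, ys, indexing="ij")
        self.nodes = np.stack([XX.ravel(), YY.ravel()], axis=1)
        nid = np.arange((n_cells + 1) ** 2).reshape(n_cells + 1, n_cells + 1)
        cells = np.stack([nid[:-1, :-1].ravel(), nid[1:, :-1].ravel(),
                          nid[1:, 1:].ravel(), nid[:-1, 1:].ravel()], axis=1)
        centers = self.nodes[cells].mean(axis=1)
        keep = shape.inside(centers)
        self.cells = cells[keep]
        # 2x2 Gauss on the reference square, bilinear shape gradients
        g = 1.0 / np.sqrt(3.0)
        gp = np.array([(-g, -g), (g, -g), (g, g), (-g, g)])
        self.wgp = 0.25 * self.hx * self.hy * np.ones(4)
        dN = np.empty((4, 4, 2))          # (gp, node, dim)
        for q, (xi, eta) in enumerate(gp):
            dN[q, :, 0] = np.array([-(1 - eta), (1 - eta),
                                    (1 + eta), -(1 + eta)]) / (2 * self.hx)
            dN[q, :, 1] = np.array([-(1 - xi), -(1 + xi),
                                    (1 + xi), (1 - xi)]) / (2 * self.hy)
        self.dN = dN

    # J0 below which the neo-Hookean log is C1-extended by a quadratic,
    # so intermediate load steps with locally inverted cells still return
    # finite energies and useful gradients
    _J0 = 0.05

    def _stabilized_nh(self, F):
        lam, mu = self.material.lam, self.material.mu
        J = np.linalg.det(F)
        j0 = self._J0
        trC = np.einsum("nij,nij->n", F, F)
        ls = np.where(J >= j0, np.log(np.maximum(J, j0)),
                      np.log(j0) + (J - j0) / j0
                      - (J - j0) ** 2 / (2 * j0 ** 2))
        dls = np.where(J >= j0, 1.0 / np.maximum(J, j0),
                       1.0 / j0 - (J - j0) / j0 ** 2)
        val = 0.5 * mu * (trC - 2.0) - mu * ls + 0.5 * lam * ls ** 2
        cof = np.empty_like(F)                 # dJ/dF for any F (2-D)
        cof[:, 0, 0] = F[:, 1, 1]
        cof[:, 0, 1] = -F[:, 1, 0]
        cof[:, 1, 0] = -F[:, 0, 1]
        cof[:, 1, 1] = F[:, 0, 0]
        P = mu * F + ((lam * ls - mu) * dls)[:, None, None] * cof
        return val, P

    def energy_grad(self, u: np.ndarray):
        uc = u[self.cells]                              # (c, 4, 2)
        F = np.einsum("cai,qaj->cqij", uc, self.dN)
        F = F + np.eye(2)
        c, q = F.shape[:2]
        if self.material.kind == "neo_hookean":
            val, P = self._stabilized_nh(F.reshape(-1, 2, 2))
        else:
            val, P = _psi_impl(self.material, F.reshape(-1, 2, 2), True)
        val = val.reshape(c, q)
        P = P.reshape(c, q, 2, 2)
        E = float((val * self.wgp).sum())
        gc = np.einsum("cqij,qaj,q->cai", P, self.dN, self.wgp)
        g = np.zeros_like(u)
        np.add.at(g, self.cells, gc)
        return E, g

    def solve(self, bc, increments: int = 4, tol: float = 1e-5,
              maxiter: int = 3000) -> np.ndarray:
        """Minimise the total energy under Dirichlet constraints.

        ``bc(nodes)`` returns ``(fixed_mask, values)`` with shape
        (n_nodes, 2) each.  The prescribed values are ramped over
        ``increments`` warm-started load steps.
        """
        fixed, values = bc(self.nodes)
        fixed = np.asarray(fixed, dtype=bool)
        values = np.asarray(values, dtype=np.float64)
        u = np.zeros_like(self.nodes)
        free = ~fixed

        for inc in range(1, increments + 1):
            fac = inc / increments
            u[fixed] = fac * values[fixed]

            def fun(x):
                u[free] = x
                E, g = self.energy_grad(u)
                return E, g[free]

            res = optimize.minimize(
                fun, u[free].copy(), jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": tol})
            u[free] = res.x
        E, g = self.energy_grad(u)
        resid = float(np.abs(g[free]).max()) if free.any() else 0.0
        if not np.isfinite(E) or resid > max(50 * tol, 1e-4) * max(1.0, abs(E)):
            raise RuntimeError(
                f"reference solve did not converge: residual {resid:.3e}")
        self.residual = resid
        return u

    def rasterize_deformed(self, u: np.ndarray, frame, resolution
                           ) -> IntensityField:
        """Fill the deformed material cells into a binary target raster."""
        from skimage.draw import polygon

        pts, origin, spacing, grid = _frame_lattice(frame, resolution)
        img = np.zeros(grid, dtype=bool)
        deformed = self.nodes + u
        for cell in self.cells:
            poly = (deformed[cell] - origin) / spacing
            rr, cc = polygon(poly[:, 0], poly[:, 1], shape=grid)
            img[rr, cc] = True
        img = ndimage.binary_closing(img, np.ones((3, 3)))
        return build_field(img.astype(float), origin, spacing,
                           binarize_threshold=0.5)


def make_bvp_target(shape: ShapeSpec, bc, material: Material,
                    n_cells: int = 48, frame=None, resolution: int = 128,
                    increments: int = 4) -> dict:
    """Deformed-configuration raster from the coarse reference solve."""
    solver = _StructuredSolver(shape, n_cells, material)
    u = solver.solve(bc, increments=increments)
    if frame is None:
        deformed = solver.nodes + u
        lo = deformed.min(axis=0) - 0.15
        hi = deformed.max(axis=0) + 0.15
        frame = list(zip(lo, hi))
    S2 = solver.rasterize_deformed(u, frame, resolution)
    S1 = rasterize(shape, "binary", resolution, frame)
    return {"S1": S1, "S2": S2, "solver": solver, "displacement": u,
            "frame": frame}


# ---------------------------------------------------------------------------
# boundary-condition presets (displacement-controlled plate problems)

def extension_bc(nodes: np.ndarray, hole_radius: float = 0.5):
    """Uniaxial extension of the plate with a fixed central hole:
    u1 = -/+1 on the left/right edges, u2 = 0 on top/bottom, u = 0 at the
    hole."""
    tol = 1e-9
    fixed = np.zeros_like(nodes, dtype=bool)
    values = np.zeros_like(nodes)
    left = nodes[:, 0] < -1 + tol
    right = nodes[:, 0] > 1 - tol
    fixed[left, 0] = True
    values[left, 0] = -1.0
    fixed[right, 0] = True
    values[right, 0] = 1.0
    tb = (nodes[:, 1] < -1 + tol) | (nodes[:, 1] > 1 - tol)
    fixed[tb, 1] = True
    r = np.linalg.norm(nodes, axis=1)
    hole = r <= hole_radius + tol
    fixed[hole] = True
    values[hole] = 0.0
    return fixed, values


def shear_contraction_bc(nodes: np.ndarray, hole_radius: float = 0.5,
                         contraction: float = 0.2, outward: bool = False):
    """Shear of the plate (u1 = 0.25 (X2+1) on the lateral edges) with the
    hole displaced radially by ``contraction`` (inward by default)."""
    tol = 1e-9
    fixed = np.zeros_like(nodes, dtype=bool)
    values = np.zeros_like(nodes)
    lr = (nodes[:, 0] < -1 + tol) | (nodes[:, 0] > 1 - tol)
    fixed[lr] = True
    values[lr, 0] = 0.25 * (nodes[lr, 1] + 1.0)
    values[lr, 1] = 0.0
    tb = (nodes[:, 1] < -1 + tol) | (nodes[:, 1] > 1 - tol)
    fixed[tb, 1] = True
    r = np.linalg.norm(nodes, axis=1)
    hole = r <= hole_radius + tol
    sign = 1.0 if outward else -1.0
    # u_r prescribed on the hole circle, extended linearly inside it
    fixed[hole] = True
    values[hole] = sign * (contraction / hole_radius) * nodes[hole]
    return fixed, values


# ---------------------------------------------------------------------------
# fixture catalogue

def plate_hole_extension(resolution: int = 128, n_cells: int = 48,
                         mode: str = "binary") -> dict:
    """Extension of the StVK plate with a central hole (Dirichlet target)."""
    shape = ShapeSpec.plate_with_hole(0.5)
    frame = [(-2.25, 2.25), (-1.25, 1.25)]
    res = (2 * resolution, resolution)
    out = make_bvp_target(shape, extension_bc, Material("stvk"),
                          n_cells=n_cells, frame=frame, resolution=res)
    if mode == "distance_rgb":
        out["S1"] = rasterize(shape, mode, res, frame)
    out["beta"] = 1.0 / 6000.0
    out["material"] = Material("stvk")
    return out


def plate_hole_shear(resolution: int = 128, n_cells: int = 48) -> dict:
    """Shear of the neo-Hookean plate while the hole contracts."""
    shape = ShapeSpec.plate_with_hole(0.5)
    frame = [(-1.3, 1.8), (-1.3, 1.3)]
    res = (int(resolution * 1.2), resolution)
    out = make_bvp_target(shape, shear_contraction_bc,
                          Material("neo_hookean"), n_cells=n_cells,
                          frame=frame, resolution=res, increments=12)
    out["beta"] = 1.0 / 6000.0
    out["material"] = Material("neo_hookean")
    return out


def plate_3holes_bending(resolution: int = 128,
                         curvature: float = 0.35) -> dict:
    """Bending of a plate with three elliptical holes.

    The hole layout is a documented approximation (one central circle
    flanked by two tilted ellipses); the target is the exact beam-bending
    diffeomorphism, so ground truth is available at every point.
    """
    shape = ShapeSpec(("box", [(-1.0, 1.0), (-0.5, 0.5)]), [
        {"center": (-0.55, 0.0), "semiaxes": (0.22, 0.13), "rotation": 0.4},
        {"center": (0.0, 0.0), "semiaxes": (0.16, 0.16)},
        {"center": (0.55, 0.0), "semiaxes": (0.22, 0.13), "rotation": -0.4},
    ])
    pair = make_pair(shape, bending(curvature), "binary", resolution)
    pair["beta"] = 1.0 / 6000.0
    pair["material"] = Material("neo_hookean")
    return pair


def disc_translation(resolution: int = 128, shift=(0.2, 0.0)) -> dict:
    disc = ShapeSpec.disc(0.5)
    return make_pair(disc, translation(np.asarray(shift)), "binary",
                     resolution, frame=[(-1.0, 1.0), (-1.0, 1.0)])


def ball_growth_pair(kappa: float = 0.05, mode: str = "growth",
                     resolution: int = 48, radius: float = 0.55,
                     raster_mode: str = "binary") -> dict:
    """3-D ball deformed by exact isotropic exponential growth/shrinkage.

    ``raster_mode="distance"`` additionally attaches interior-distance
    intensity versions (keys ``S1_distance``/``S2_distance``), which carry
    alignment information everywhere in the body, not just at its surface.
    """
    ball = ShapeSpec.ball(radius)
    mmap = isotropic_growth(kappa, 3, mode=mode)
    pair = make_pair(ball, mmap, "binary", resolution,
                     frame=[(-1.0, 1.0)] * 3)
    if raster_mode in ("distance", "distance_rgb",
                       "occupancy_distance"):
        frame = pair["frame"]
        pair["S1_distance"] = rasterize(ball, raster_mode, resolution, frame)
        pair["S2_distance"] = rasterize(
            ball, raster_mode, resolution, frame,
            inside_fn=lambda x: ball.inside(mmap.inverse(x)))
    pair["kappa_true"] = kappa
    pair["mode"] = mode
    return pair


FIXTURES = {
    "plate_hole_extension": plate_hole_extension,
    "plate_hole_shear": plate_hole_shear,
    "plate_3holes_bending": plate_3holes_bending,
    "disc_translation": disc_translation,
    "ball_growth": lambda **kw: ball_growth_pair(mode="growth", **kw),
    "ball_shrinkage": lambda **kw: ball_growth_pair(mode="shrinkage", **kw),
}
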