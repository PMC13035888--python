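"""Axisymmetric finite-element forward model of flat-punch indentation.

A rigid, flat-ended cylindrical punch indents an incompressible hyperelastic
cylinder.  The discretisation uses 4-node quadrilaterals with bilinear
displacements and an element-constant pressure field enforcing
incompressibility (the axisymmetric analogue of linear hybrid bricks),
solved monolithically by Newton's method in a total-Lagrangian setting.

Boundary conditions follow the physical test: the bottom face is fixed
vertically only (radially free), the symmetry axis is fixed radially, and
the punch is modelled by prescribing the vertical displacement on the nodes
of its footprint (radial sliding free — frictionless contact).  A flat
punch has a known constant contact patch, so no contact search is needed;
non-adhesion is enforced by releasing any footprint node whose reaction
turns tensile and re-solving the step.

Element residuals are exact (assembled from the first Piola–Kirchhoff
stress); the consistent tangent is obtained by symmetric finite differences
of the element residual, batched over all elements and perturbation
directions.  Robustness helpers: a residual-norm backtracking line search,
a secant predictor between load steps, and adaptive step bisection on
divergence.

The module also provides Richardson extrapolation for mesh-convergence
studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .constitutive import HyperelasticParams, initial_shear_modulus
from .curves import ForceDisplacementCurve
from .mesh import AxisymMesh

log = logging.getLogger(__name__)

__all__ = [
    "FESolution",
    "StepResult",
    "RichardsonResult",
    "solve_indentation",
    "richardson_extrapolate",
    "mesh_study",
]

_GP = 1.0 / np.sqrt(3.0)
_QP = np.array([[-_GP, -_GP], [_GP, -_GP], [_GP, _GP], [-_GP, _GP]])  # 2x2 Gauss
_NODES_XI = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])


def _shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear shape functions and parent-space gradients at points xi."""
    N = 0.25 * (1 + xi[:, None, 0] * _NODES_XI[None, :, 0]) * (
        1 + xi[:, None, 1] * _NODES_XI[None, :, 1]
    )
    dN = np.empty((xi.shape[0], 4, 2))
    dN[:, :, 0] = 0.25 * _NODES_XI[None, :, 0] * (1 + xi[:, None, 1] * _NODES_XI[None, :, 1])
    dN[:, :, 1] = 0.25 * _NODES_XI[None, :, 1] * (1 + xi[:, None, 0] * _NODES_XI[None, :, 0])
    return N, dN


class _Geometry:
    """Mesh-dependent quadrature data, shared across material evaluations."""

    def __init__(self, mesh: AxisymMesh):
        self.mesh = mesh
        Xe = mesh.nodes[mesh.elems]  # (ne, 4, 2)
        N, dN = _shape(_QP)  # (nq,4), (nq,4,2)
        self.N = N
        J = np.einsum("qad,eai->eqid", dN, Xe)  # dX/dxi
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("mesh contains non-positively oriented elements")
        Jinv = np.empty_like(J)
        Jinv[..., 0, 0] = J[..., 1, 1] / detJ
        Jinv[..., 1, 1] = J[..., 0, 0] / detJ
        Jinv[..., 0, 1] = -J[..., 0, 1] / detJ
        Jinv[..., 1, 0] = -J[..., 1, 0] / detJ
        self.dNdX = np.einsum("qad,eqdj->eqaj", dN, Jinv)  # (ne, nq, 4, 2)
        self.Rq = np.einsum("qa,ea->eq", N, Xe[:, :, 0])  # radius at quad points
        self.w = detJ * 2.0 * np.pi * self.Rq  # unit Gauss weights
        ne, nn = mesh.n_elems, mesh.n_nodes
        ed = np.empty((ne, 9), dtype=np.int64)  # 8 displacement dofs + pressure
        ed[:, 0:8:2] = 2 * mesh.elems
        ed[:, 1:8:2] = 2 * mesh.elems + 1
        ed[:, 8] = 2 * nn + np.arange(ne)
        self.edofs = ed
        self.rows = np.repeat(ed, 9, axis=1).ravel()
        self.cols = np.tile(ed, (1, 9)).ravel()
        self.ndof = 2 * nn + ne

    def reference_volume(self) -> float:
        return float(self.w.sum())


_GEOM_CACHE: dict[int, tuple[AxisymMesh, _Geometry]] = {}


def _geometry(mesh: AxisymMesh) -> _Geometry:
    hit = _GEOM_CACHE.get(id(mesh))
    if hit is not None and hit[0] is mesh:
        return hit[1]
    g = _Geometry(mesh)
    if len(_GEOM_CACHE) > 32:
        _GEOM_CACHE.clear()
    _GEOM_CACHE[id(mesh)] = (mesh, g)
    return g


def _elem_residual(
    geo: _Geometry, params: HyperelasticParams, ue: np.ndarray, pe: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Element residuals (internal forces and volume constraint).

    ``ue``: (..., ne, 4, 2) element nodal displacements; ``pe``: (..., ne)
    element pressures; leading axes batch independent evaluations (used by
    the finite-difference tangent).  Returns (fu (..., ne, 4, 2),
    g (..., ne), J (..., ne, nq)).  Invalid states (inverted elements,
    non-positive hoop stretch for a stretch-based law) yield non-finite
    entries that the Newton driver treats as divergence.
    """
    with np.errstate(all="ignore"):
        Hg = np.einsum("...eai,eqaj->...eqij", ue, geo.dNdX)
        Fp = Hg.copy()
        Fp[..., 0, 0] += 1.0
        Fp[..., 1, 1] += 1.0
        Ft = 1.0 + np.einsum("qa,...ea->...eq", geo.N, ue[..., 0]) / geo.Rq

        if params.model == "yeoh":
            c1, c2, c3 = params.C
            I1 = np.einsum("...eqij,...eqij->...eq", Fp, Fp) + Ft**2
            x = I1 - 3.0
            coef = 2.0 * (c1 + 2.0 * c2 * x + 3.0 * c3 * x**2)
            Piso = coef[..., None, None] * Fp
            Pt = coef * Ft
        else:
            mu = np.asarray(params.mu)
            al = np.asarray(params.alpha)
            C = np.einsum("...eqki,...eqkj->...eqij", Fp, Fp)
            shp = C.shape[:-2]
            evals, evecs = np.linalg.eigh(C.reshape(-1, 2, 2))
            lam = np.sqrt(np.maximum(evals, 1e-30))  # (m, 2)
            beta = np.einsum("mak,k->ma", lam[..., None] ** (al - 1.0), mu)
            coefa = beta / lam
            S = np.einsum("ma,mia,mja->mij", coefa, evecs, evecs).reshape(*shp, 2, 2)
            Piso = np.einsum("...eqik,...eqkj->...eqij", Fp, S)
            Pt = np.einsum("...eqk,k->...eq", Ft[..., None] ** (al - 1.0), mu)

        detFp = Fp[..., 0, 0] * Fp[..., 1, 1] - Fp[..., 0, 1] * Fp[..., 1, 0]
        J = Ft * detFp
        cof = np.empty_like(Fp)  # d(detFp)/dFp
        cof[..., 0, 0] = Fp[..., 1, 1]
        cof[..., 1, 1] = Fp[..., 0, 0]
        cof[..., 0, 1] = -Fp[..., 1, 0]
        cof[..., 1, 0] = -Fp[..., 0, 1]
        P = Piso + (pe[..., None] * Ft)[..., None, None] * cof
        Pt = Pt + pe[..., None] * detFp

        fu = np.einsum("...eq,...eqij,eqaj->...eai", geo.w, P, geo.dNdX)
        fu[..., 0] += np.einsum("...eq,qa->...ea", geo.w * Pt / geo.Rq, geo.N)
        g = np.einsum("eq,...eq->...e", geo.w, J - 1.0)
    return fu, g, J


class _System:
    """Residual/tangent assembly for one mesh + material pair."""

    def __init__(self, mesh: AxisymMesh, params: HyperelasticParams):
        self.mesh = mesh
        self.params = params
        self.geo = _geometry(mesh)
        mu0 = abs(initial_shear_modulus(params))
        if params.model == "yeoh":
            mu0 = max(mu0, 2.0 * max(abs(c) for c in params.C))
        self._h_u = 1e-7  # mm
        self._h_p = 1e-7 * max(mu0, 1e-9)  # N/mm^2
        #: rim-contact penalty stiffness, N/mm — stiff relative to the
        #: punch structural stiffness ~ 2*E0*a so penetrations stay far
        #: below the mesh resolution
        self.pen_k = 1e3 * max(mu0, 1e-9) * mesh.a

    def _gather(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nn = self.mesh.n_nodes
        u = x[: 2 * nn].reshape(nn, 2)
        return u[self.mesh.elems], x[2 * nn :]

    def residual(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global residual vector and quad-point volume ratios J."""
        ue, pe = self._gather(x)
        fu, g, J = _elem_residual(self.geo, self.params, ue, pe)
        r = np.zeros(self.geo.ndof)
        np.add.at(r, self.geo.edofs[:, :8], fu.reshape(-1, 8))
        r[2 * self.mesh.n_nodes :] = g
        return r, J

    def tangent(self, x: np.ndarray) -> coo_matrix:
        """Consistent tangent by symmetric differencing of element residuals,
        batched over the 18 perturbed configurations."""
        ue, pe = self._gather(x)
        ne = self.mesh.n_elems
        hu, hp = self._h_u, self._h_p
        ue_b = np.broadcast_to(ue, (16,) + ue.shape).copy()
        for j in range(8):
            a, i = divmod(j, 2)
            ue_b[2 * j, :, a, i] += hu
            ue_b[2 * j + 1, :, a, i] -= hu
        fu_b, g_b, _ = _elem_residual(self.geo, self.params, ue_b, np.broadcast_to(pe, (16, ne)))
        pe_b = np.vstack([pe + hp, pe - hp])
        fu_p, g_p, _ = _elem_residual(
            self.geo, self.params, np.broadcast_to(ue, (2,) + ue.shape), pe_b
        )
        K = np.empty((ne, 9, 9))
        for j in range(8):
            K[:, :8, j] = (fu_b[2 * j] - fu_b[2 * j + 1]).reshape(ne, 8) / (2 * hu)
            K[:, 8, j] = (g_b[2 * j] - g_b[2 * j + 1]) / (2 * hu)
        K[:, :8, 8] = (fu_p[0] - fu_p[1]).reshape(ne, 8) / (2 * hp)
        K[:, 8, 8] = (g_p[0] - g_p[1]) / (2 * hp)
        return coo_matrix(
            (K.ravel(), (self.geo.rows, self.geo.cols)), shape=(self.geo.ndof, self.geo.ndof)
        )


class _PunchPenalty:
    """Unilateral penalty keeping top-surface nodes outside the rigid punch.

    Footprint nodes are handled by prescribed displacements; the free
    surface just outside the rim can bulge, flow inward under the punch
    face and — at deep indentation — penetrate it.  Penalised nodes are
    pushed out of the punch along the gradient of the signed distance to a
    rim-filleted punch profile (flat face for r <= a - rho, quarter-circle
    fillet of radius rho at the rim, cylindrical side wall above), with a
    quadratically blended force law so grazing contact stays smooth.  Nodes
    entering from the side are thus expelled radially — they wrap around
    the rim — instead of being slammed down onto the face plane.
    """

    def __init__(
        self,
        nodes: np.ndarray,
        coords: np.ndarray,
        zface: float,
        a: float,
        k: float,
        fillet: float = 0.1,
    ):
        self.nodes = nodes
        self.R = coords[nodes, 0]
        self.Z = coords[nodes, 1]
        self.zface = zface
        self.a = a
        self.k = k
        self.rho = min(fillet, 0.5 * a)
        self.g0 = 5e-3  # mm, force-law regularisation depth

    def _eval(self, x: np.ndarray):
        """Penetration depth g, outward unit normal n, and corner data."""
        rho = self.rho
        r = self.R + x[2 * self.nodes]
        z = self.Z + x[2 * self.nodes + 1]
        u = r - (self.a - rho)  # radial offset from fillet centre
        v = (self.zface + rho) - z  # downward offset from fillet centre
        corner = (u > 0) & (v > 0)
        dist = np.sqrt(np.where(corner, u**2 + v**2, 1.0))
        sdf = np.where(corner, dist - rho, np.maximum(u, v) - rho)
        n = np.empty((self.nodes.size, 2))
        side = (~corner) & (u >= v)
        n[:, 0] = np.where(corner, u / dist, np.where(side, 1.0, 0.0))
        n[:, 1] = np.where(corner, -v / dist, np.where(side, 0.0, -1.0))
        g = np.maximum(-sdf, 0.0)
        return g, n, corner, dist

    def _q(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g0 = self.g0
        q = np.where(g < g0, g**2 / (2 * g0), g - g0 / 2)
        dq = np.where(g < g0, g / g0, 1.0)
        return q, dq

    def add_residual(self, x: np.ndarray, res: np.ndarray) -> None:
        g, n, _, _ = self._eval(x)
        q, _ = self._q(g)
        f = self.k * q[:, None] * n  # external force pushing the node out
        res[2 * self.nodes] -= f[:, 0]
        res[2 * self.nodes + 1] -= f[:, 1]

    def stiffness_entries(self, x: np.ndarray):
        """(rows, cols, vals) of the penalty contribution to the tangent.

        d(-f)/dp = k*dq * n n^T - k*q * dn/dp, with dn/dp nonzero (curvature
        of the fillet) only in the corner sector.
        """
        g, n, corner, dist = self._eval(x)
        q, dq = self._q(g)
        act = g > 0
        if not act.any():
            return np.array([], int), np.array([], int), np.array([])
        idx = np.where(act)[0]
        nn_ = n[idx]
        blk = self.k * dq[idx, None, None] * nn_[:, :, None] * nn_[:, None, :]
        curv = np.where(corner[idx], self.k * q[idx] / dist[idx], 0.0)
        eye = np.eye(2)
        blk -= curv[:, None, None] * (eye - nn_[:, :, None] * nn_[:, None, :])
        dofs = np.stack([2 * self.nodes[idx], 2 * self.nodes[idx] + 1], axis=1)
        rows = np.repeat(dofs, 2, axis=1).ravel()
        cols = np.tile(dofs, (1, 2)).ravel()
        return rows, cols, blk.ravel()

    def total_force(self, x: np.ndarray) -> float:
        """Vertical punch load carried by the penalised (rim) nodes."""
        g, n, _, _ = self._eval(x)
        q, _ = self._q(g)
        return float((self.k * q * (-n[:, 1]).clip(0.0)).sum())


def _newton(
    sys_: _System,
    x: np.ndarray,
    fixed: np.ndarray,
    pen: _PunchPenalty | None = None,
    tol_rel: float = 1e-9,
    tol_abs: float = 1e-12,
    max_iter: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """Newton iteration at fixed prescribed dofs (already set in ``x``),
    with a residual-norm backtracking line search.

    Returns (x, residual, J, converged, iterations).
    """
    free = np.ones(sys_.geo.ndof, dtype=bool)
    free[fixed] = False

    def _residual(xv):
        r, J = sys_.residual(xv)
        if pen is not None:
            pen.add_residual(xv, r)
        return r, J

    r, J = _residual(x)
    rn = np.linalg.norm(r[free])
    if not np.isfinite(rn):
        return x, r, J, False, 0
    r0 = rn
    for it in range(max_iter + 1):
        if rn <= max(tol_rel * r0, tol_abs):
            return x, r, J, True, it
        if it == max_iter:
            return x, r, J, False, it
        K = sys_.tangent(x)
        if not np.isfinite(K.data).all():
            return x, r, J, False, it
        if pen is not None:
            pr, pc, pv = pen.stiffness_entries(x)
            if pv.size:
                K = K + coo_matrix((pv, (pr, pc)), shape=(sys_.geo.ndof, sys_.geo.ndof))
        Kff = K.tocsc()[free][:, free].tocsc()
        try:
            dx = splu(Kff).solve(-r[free])
        except RuntimeError:
            return x, r, J, False, it
        if not np.isfinite(dx).all():
            return x, r, J, False, it
        # backtracking: keep halving while the residual norm worsens
        step = 1.0
        for _ in range(6):
            x_try = x.copy()
            x_try[free] += step * dx
            r_try, J_try = _residual(x_try)
            rn_try = np.linalg.norm(r_try[free])
            if np.isfinite(rn_try) and rn_try < rn * (1.0 + 1e-12):
                break
            step *= 0.5
        else:
            if not np.isfinite(rn_try):
                return x, r, J, False, it
        x, r, J, rn = x_try, r_try, J_try, rn_try
    return x, r, J, False, max_iter


@dataclass
class StepResult:
    """Converged state of one load step."""

    delta: float  # punch displacement, mm
    force: float  # punch reaction, N (positive = compressive)
    u: np.ndarray  # nodal displacements (n_nodes, 2), mm
    p: np.ndarray  # element pressures, N/mm^2
    converged: bool
    newton_iters: int
    volume_error_elem: float  # max |mean element J - 1|
    volume_error_qp: float  # max |J - 1| over quadrature points
    released_nodes: np.ndarray  # footprint nodes released as non-adhesive


@dataclass
class FESolution:
    """Per-step fields and reactions of an indentation solve."""

    steps: list[StepResult] = field(default_factory=list)
    completed: bool = True

    @property
    def deltas(self) -> np.ndarray:
        return np.array([s.delta for s in self.steps])

    @property
    def forces(self) -> np.ndarray:
        return np.array([s.force for s in self.steps])

    @property
    def max_volume_error(self) -> float:
        """Largest element volume-change error |J_e - 1| over all steps."""
        return max((s.volume_error_elem for s in self.steps), default=0.0)

    @property
    def max_volume_error_qp(self) -> float:
        return max((s.volume_error_qp for s in self.steps), default=0.0)


def solve_indentation(
    mesh: AxisymMesh,
    params: HyperelasticParams,
    delta_max: float = 3.0,
    n_steps: int = 30,
    top_condition: str = "punch",
    max_halvings: int = 4,
) -> tuple[ForceDisplacementCurve, FESolution]:
    """Drive the punch to ``delta_max`` in ``n_steps`` equal increments.

    ``top_condition="punch"`` prescribes the vertical displacement on the
    punch footprint only (the production contact model); ``"full"``
    compresses the entire top face homogeneously (patch test).  Diverged
    increments are retried with up to ``max_halvings`` bisections; if a
    target step still fails, the partial curve is returned with
    ``completed=False``.  The returned curve includes the (0, 0) point.
    """
    if not (0.0 < delta_max < mesh.H):
        raise ValueError("need 0 < delta_max < sample height")
    if top_condition not in ("punch", "full"):
        raise ValueError("top_condition must be 'punch' or 'full'")
    sys_ = _System(mesh, params)
    nn = mesh.n_nodes
    contact = mesh.top_contact if top_condition == "punch" else mesh.top
    base_fixed = np.concatenate([2 * mesh.bottom + 1, 2 * mesh.axis])

    x = np.zeros(sys_.geo.ndof)
    x_prev: np.ndarray | None = None
    sol = FESolution()
    sol.steps.append(
        StepResult(
            0.0, 0.0, np.zeros((nn, 2)), np.zeros(mesh.n_elems), True, 0, 0.0, 0.0,
            np.array([], dtype=int),
        )
    )
    targets = delta_max * np.arange(1, n_steps + 1) / n_steps
    delta_cur = 0.0

    for target in targets:
        # secant predictor from the previous increment
        x0 = x.copy()
        if x_prev is not None:
            x0 += x - x_prev
        ok, x_new, result = _advance(sys_, x0, x, base_fixed, contact, delta_cur, target, max_halvings)
        if not ok:
            log.warning("indentation solve stalled at delta=%.4f mm", delta_cur)
            sol.completed = False
            break
        x_prev, x = x, x_new
        delta_cur = target
        sol.steps.append(result)

    disp = np.array([s.delta for s in sol.steps])
    force = np.array([s.force for s in sol.steps])
    return ForceDisplacementCurve(disp, force), sol


def _advance(sys_, x0, x_fallback, base_fixed, contact, d_from, d_to, max_halvings, depth=0):
    """Advance to punch depth d_to (trying the predictor state ``x0`` first,
    falling back to ``x_fallback`` when bisecting); returns
    (ok, x, StepResult).

    The contact active set over the top surface is resolved per step: active
    nodes with tensile reactions, or that have slid radially out past the
    punch rim, are released; inactive top nodes whose deformed position would
    penetrate the punch face (current r < a, z above the face plane) are
    added.  For the patch-test condition ("full" top) the whole face is
    prescribed and the geometric updates never trigger.
    """
    mesh = sys_.mesh
    geo = sys_.geo
    is_punch = len(contact) < len(mesh.top)
    active = contact.copy()
    zface = mesh.H - d_to
    for _attempt in range(len(contact) + 1):
        pen = None
        if is_punch:
            # penalty guards every top node not currently pinned to the punch,
            # including footprint nodes released as non-adhesive
            pen = _PunchPenalty(
                np.setdiff1d(mesh.top, active), mesh.nodes, zface, mesh.a, sys_.pen_k
            )
        x_try = x0.copy()
        x_try[2 * active + 1] = -d_to
        fixed = np.concatenate([base_fixed, 2 * active + 1])
        x_new, r, J, conv, iters = _newton(sys_, x_try, fixed, pen)
        if not conv:
            break
        rz = r[2 * active + 1]
        drop = rz > 1e-9 * max(1.0, np.abs(rz).max())  # tensile reaction
        if not drop.any():
            force = -float(rz.sum())
            if pen is not None:
                force += pen.total_force(x_new)
            nn = mesh.n_nodes
            Jbar = np.einsum("eq,eq->e", geo.w, J) / geo.w.sum(axis=1)
            step = StepResult(
                d_to,
                force,
                x_new[: 2 * nn].reshape(nn, 2).copy(),
                x_new[2 * nn :].copy(),
                True,
                iters,
                float(np.abs(Jbar - 1.0).max()),
                float(np.abs(J - 1.0).max()),
                np.setdiff1d(contact, active),
            )
            return True, x_new, step
        active = np.setdiff1d(active, active[drop])
        log.info("released %d tensile footprint node(s) at delta=%.3f", int(drop.sum()), d_to)
        x0 = x_new  # warm start the re-solve
    if depth >= max_halvings:
        return False, x_fallback, None
    mid = 0.5 * (d_from + d_to)
    ok, x_mid, _ = _advance(
        sys_, x_fallback.copy(), x_fallback, base_fixed, contact, d_from, mid, max_halvings, depth + 1
    )
    if not ok:
        return False, x_fallback, None
    return _advance(sys_, x_mid.copy(), x_mid, base_fixed, contact, mid, d_to, max_halvings, depth + 1)


# ---------------------------------------------------------------------------
# Richardson extrapolation
# ---------------------------------------------------------------------------


def mesh_study(
    params: HyperelasticParams,
    n_coarse: int = 10,
    ratio: int = 2,
    delta: float = 2.0,
    n_steps: int = 20,
    R_s: float = 10.0,
    H: float = 10.0,
    a: float = 2.5,
    grading: float = 3.0,
) -> "RichardsonResult":
    """Three-grid Richardson convergence study of the punch force.

    Solves the indentation problem on ``n_coarse``, ``n_coarse*ratio`` and
    ``n_coarse*ratio**2`` square grids and extrapolates the force at depth
    ``delta``.  The default depth of 2 mm (20 % nominal strain) sits inside
    the solver's asymptotic convergence range; at full 30 % indentation the
    discrete rim-contact state (node-wise release and penalty engagement)
    flips between refinement levels and the force family is generally not
    asymptotic, which :func:`richardson_extrapolate` then reports as a
    range violation.
    """
    from .mesh import build_mesh  # local import to avoid cycle confusion

    vals = []
    for k in range(3):
        n = n_coarse * ratio**k
        mesh = build_mesh(R_s, H, a, n, n, grading)
        curve, sol = solve_indentation(mesh, params, delta_max=delta, n_steps=n_steps)
        if not sol.completed:
            raise RuntimeError(f"mesh-study solve on the {n}x{n} grid did not complete")
        vals.append(float(curve.force[-1]))
    return richardson_extrapolate(vals, float(ratio))


@dataclass(frozen=True)
class RichardsonResult:
    """Observed convergence order and zero-mesh-size limit of a 3-grid family."""

    values: tuple[float, float, float]  # coarse, medium, fine
    ratio: float
    order: float
    extrapolated: float


def richardson_extrapolate(values, ratio: float = 2.0) -> RichardsonResult:
    """Richardson extrapolation from solutions on three systematically
    refined grids (coarse, medium, fine) with constant refinement ratio.

    order p = ln((f_c - f_m)/(f_m - f_f)) / ln(r);
    limit = f_f + (f_f - f_m)/(r**p - 1).
    Oscillatory sequences (differences of opposite sign) violate the
    asymptotic-range assumption and raise a ValueError.
    """
    fc, fm, ff = (float(v) for v in values)
    if ratio <= 1.0:
        raise ValueError("refinement ratio must exceed 1")
    d1, d2 = fc - fm, fm - ff
    if d1 == 0.0 or d2 == 0.0 or d1 * d2 < 0.0:
        raise ValueError("grid values are not monotone: outside the asymptotic range")
    p = np.log(d1 / d2) / np.log(ratio)
    extrap = ff + (ff - fm) / (ratio**p - 1.0)
    if not np.isfinite(extrap):
        raise ValueError("extrapolated value is not finite")
    return RichardsonResult((fc, fm, ff), ratio, float(p), float(extrap))
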