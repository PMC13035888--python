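"""Inverse finite-element calibration of hyperelastic parameters.

Given a measured (or synthetic) indentation force–displacement curve, the
material coefficients are found by minimising the sum of squared force
residuals between the FE forward model and the measurement, using a
bespoke Nelder–Mead simplex (derivative-free: the forward model is noisy
at solver tolerance and may fail for extreme trial parameters).

The objective is formulated in force rather than apparent stress: with a
constant punch area the two differ only by the factor ``(pi a^2)^-2``, so
the minimisers coincide.  Forward solves run on a coarse mesh inside the
loop, with a finer confirmation solve at the end; results carry the fit
error (normalised RMS force mismatch, %) and a Drucker stability verdict
for the fitted coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constitutive import HyperelasticParams
from .curves import ForceDisplacementCurve, regularize
from .fe import solve_indentation
from .mesh import AxisymMesh, build_mesh
from .stability import StabilityReport, drucker_scan

log = logging.getLogger(__name__)

__all__ = [
    "NelderMeadResult",
    "CalibrationResult",
    "nelder_mead",
    "ForwardModel",
    "objective_rss",
    "fit_error_percent",
    "calibrate",
    "MESH_PRESETS",
]

#: mesh density presets (n_r, n_z, grading) for the standard sample geometry
MESH_PRESETS: dict[str, tuple[int, int, float]] = {
    "coarse": (8, 8, 3.0),
    "medium": (20, 20, 3.0),
    "fine": (40, 40, 3.0),
}


# ---------------------------------------------------------------------------
# Nelder–Mead simplex
# ---------------------------------------------------------------------------


@dataclass
class NelderMeadResult:
    x: np.ndarray
    fun: float
    iterations: int
    simplex_diameter: float
    converged: bool
    history: list[float] = field(default_factory=list)  # best objective per iteration


def nelder_mead(
    objective,
    x0: np.ndarray,
    init_scale: float = 0.2,
    tol_x: float = 1e-4,
    tol_f: float = 1e-12,
    max_iter: int = 2000,
) -> NelderMeadResult:
    """Minimise ``objective`` by the Nelder–Mead simplex method.

    Standard coefficients: reflection 1, expansion 2, contraction 0.5,
    shrink 0.5.  The initial simplex perturbs each coordinate of ``x0`` by
    ``init_scale`` relatively (or 1e-4 absolutely for zero coordinates).
    Stops when the simplex diameter falls below ``tol_x`` relative to the
    best-vertex norm (absolute for a zero best vertex), when the objective
    spread falls below ``tol_f``, or at ``max_iter``.  Vertices where the
    objective is non-finite are treated as infinitely bad; a non-finite
    objective at ``x0`` itself is an error.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is not finite at the initial point")

    simplex = [x0]
    for i in range(n):
        xi = x0.copy()
        xi[i] += init_scale * xi[i] if xi[i] != 0.0 else 1e-4
        simplex.append(xi)
    simplex = np.asarray(simplex)
    fvals = np.array([f0] + [_safe(objective, v) for v in simplex[1:]])

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]
        history.append(float(fvals[0]))

        diam = float(np.max(np.linalg.norm(simplex[1:] - simplex[0], axis=1)))
        scale = max(np.linalg.norm(simplex[0]), 1e-30)
        if diam / scale < tol_x or (np.isfinite(fvals[-1]) and fvals[-1] - fvals[0] < tol_f):
            converged = True
            break

        centroid = simplex[:-1].mean(axis=0)
        xr = centroid + (centroid - simplex[-1])  # reflection
        fr = _safe(objective, xr)
        if fr < fvals[0]:
            xe = centroid + 2.0 * (centroid - simplex[-1])  # expansion
            fe = _safe(objective, xe)
            simplex[-1], fvals[-1] = (xe, fe) if fe < fr else (xr, fr)
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:  # outside contraction
                xc = centroid + 0.5 * (xr - centroid)
            else:  # inside contraction
                xc = centroid + 0.5 * (simplex[-1] - centroid)
            fc = _safe(objective, xc)
            if fc < min(fr, fvals[-1]):
                simplex[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                simplex[1:] = simplex[0] + 0.5 * (simplex[1:] - simplex[0])
                fvals[1:] = [_safe(objective, v) for v in simplex[1:]]

    order = np.argsort(fvals, kind="stable")
    simplex, fvals = simplex[order], fvals[order]
    diam = float(np.max(np.linalg.norm(simplex[1:] - simplex[0], axis=1)))
    return NelderMeadResult(simplex[0], float(fvals[0]), it, diam, converged, history)


def _safe(objective, x: np.ndarray) -> float:
    try:
        f = objective(x)
    except Exception:  # forward-model failure: reject the vertex
        log.debug("objective evaluation failed at %s", x, exc_info=True)
        return np.inf
    return f if np.isfinite(f) else np.inf


# ---------------------------------------------------------------------------
# forward model and objective
# ---------------------------------------------------------------------------


class ForwardModel:
    """Cached FE forward solver on a fixed mesh and displacement schedule."""

    def __init__(
        self,
        mesh: AxisymMesh | None = None,
        preset: str = "coarse",
        delta_max: float = 3.0,
        n_steps: int = 8,
    ):
        if mesh is None:
            nr, nz, gr = MESH_PRESETS[preset]
            mesh = build_mesh(n_r=nr, n_z=nz, grading=gr)
        self.mesh = mesh
        self.delta_max = delta_max
        self.n_steps = n_steps
        self._cache: dict[tuple, np.ndarray] = {}

    @property
    def deltas(self) -> np.ndarray:
        """The displacement grid of the model, including 0."""
        return self.delta_max * np.arange(self.n_steps + 1) / self.n_steps

    def forces(self, params: HyperelasticParams) -> np.ndarray:
        """Punch force at each displacement step; raises if the solve fails."""
        key = (params.model, params.C if params.model == "yeoh" else (params.mu, params.alpha))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        curve, sol = solve_indentation(
            self.mesh, params, delta_max=self.delta_max, n_steps=self.n_steps
        )
        if not sol.completed:
            raise RuntimeError("forward FE solve did not complete")
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[key] = curve.force
        return curve.force

    def curve(self, params: HyperelasticParams) -> ForceDisplacementCurve:
        return ForceDisplacementCurve(self.deltas.copy(), self.forces(params))


def objective_rss(
    params: HyperelasticParams,
    exp_curve: ForceDisplacementCurve,
    forward: ForwardModel,
) -> float:
    """Sum of squared force residuals (N^2) on the forward model's steps.

    ``exp_curve`` must already be sampled on ``forward.deltas`` (use
    :func:`indentfit.curves.regularize` first).  A failed forward solve
    returns +inf so the optimiser rejects the vertex.
    """
    if exp_curve.displacement.shape != forward.deltas.shape or not np.allclose(
        exp_curve.displacement, forward.deltas, rtol=0, atol=1e-10
    ):
        raise ValueError("experimental curve is not on the forward model's steps")
    try:
        fcal = forward.forces(params)
    except RuntimeError:
        log.info("forward solve failed; rejecting vertex")
        return np.inf
    return float(np.sum((fcal - exp_curve.force) ** 2))


def fit_error_percent(
    sim_curve: ForceDisplacementCurve, exp_curve: ForceDisplacementCurve
) -> float:
    """Normalised RMS force mismatch: 100 * RMS(F_cal - F_exp) / max|F_exp|."""
    if sim_curve.displacement.shape != exp_curve.displacement.shape or not np.allclose(
        sim_curve.displacement, exp_curve.displacement, rtol=0, atol=1e-10
    ):
        raise ValueError("curves are not on a shared grid")
    peak = np.abs(exp_curve.force).max()
    if peak == 0.0:
        raise ValueError("experimental curve has zero peak force")
    rms = np.sqrt(np.mean((sim_curve.force - exp_curve.force) ** 2))
    return float(100.0 * rms / peak)


# ---------------------------------------------------------------------------
# calibration driver
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Outcome of an inverse-FE material calibration."""

    model: str
    params: HyperelasticParams
    objective: float  # sum of squared force residuals, N^2
    fit_error_percent: float
    iterations: int
    simplex_diameter: float
    converged: bool
    history: list[float]
    stability: StabilityReport

    @property
    def stable(self) -> bool:
        return self.stability.overall_stable


def calibrate(
    exp_curve: ForceDisplacementCurve,
    model: str,
    x0: HyperelasticParams | np.ndarray,
    forward: ForwardModel | None = None,
    confirm: ForwardModel | None = None,
    tol_x: float = 1e-4,
    tol_f: float = 1e-12,
    max_iter: int = 2000,
) -> CalibrationResult:
    """Calibrate ``model`` ("yeoh" | "ogden3") coefficients to a measured
    indentation curve.

    The coefficients are unconstrained during the search; physical
    admissibility is screened afterwards with a Drucker stability scan whose
    verdict is attached to the result.  ``forward`` is the in-loop (coarse)
    solver; ``confirm``, when given, re-evaluates the fitted parameters on a
    finer mesh for the reported fit error.
    """
    if forward is None:
        forward = ForwardModel(preset="coarse")
    if isinstance(x0, HyperelasticParams):
        if x0.model != model:
            raise ValueError("seed parameter model differs from requested model")
        x0 = x0.to_vector()

    exp_on_steps = regularize(exp_curve, forward.deltas)

    def obj(x: np.ndarray) -> float:
        return objective_rss(HyperelasticParams.from_vector(model, x), exp_on_steps, forward)

    nm = nelder_mead(obj, x0, tol_x=tol_x, tol_f=tol_f, max_iter=max_iter)
    fitted = HyperelasticParams.from_vector(model, nm.x)

    checker = confirm if confirm is not None else forward
    exp_on_confirm = regularize(exp_curve, checker.deltas)
    err = fit_error_percent(checker.curve(fitted), exp_on_confirm)
    report = drucker_scan(fitted)
    if not report.overall_stable:
        log.warning("fitted %s parameters are Drucker unstable", model)
    return CalibrationResult(
        model, fitted, nm.fun, err, nm.iterations, nm.simplex_diameter, nm.converged,
        nm.history, report,
    )
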