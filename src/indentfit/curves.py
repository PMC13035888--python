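"""Indentation curve processing.

Raw force–displacement records come off the rig with coarse force
resolution relative to the displacement resolution, so they are first
regularised onto a common displacement grid by shape-preserving (monotone
piecewise-cubic) interpolation.  Regularised curves support point-wise
group statistics (mean and sample std), conversion to apparent
stress–strain via the punch area and sample thickness, and extraction of
the apparent Young's modulus as the least-squares slope over a designated
linear strain region.

The two default linear regions are 3.75–11.5 % and 22.5–30 % strain; the
apparent modulus is punch pressure over nominal strain with no half-space
geometry correction (see :mod:`docs/methods` for the rationale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

log = logging.getLogger(__name__)

__all__ = [
    "ForceDisplacementCurve",
    "StressStrainCurve",
    "LinearRegion",
    "FIRST_LINEAR_REGION",
    "SECOND_LINEAR_REGION",
    "DEFAULT_GRID",
    "regularize",
    "pointwise_mean",
    "to_stress_strain",
    "linear_region_modulus",
    "two_region_moduli",
]


@dataclass(frozen=True)
class ForceDisplacementCurve:
    """An ordered sampled indentation curve (displacement mm, force N)."""

    displacement: np.ndarray
    force: np.ndarray
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if self.time is not None:
            t = np.asarray(self.time, dtype=float)
            object.__setattr__(self, "time", t)
            if t.shape != d.shape:
                raise ValueError("time and displacement lengths differ")
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("displacement and force must be equal-length 1-d arrays")
        if d.size and d[0] < 0:
            raise ValueError("displacement must start at >= 0")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
            raise ValueError("curve contains non-finite values")

    def __len__(self) -> int:
        return self.displacement.size


@dataclass(frozen=True)
class StressStrainCurve:
    """Apparent stress (N/mm^2) vs nominal strain (dimensionless)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.strain, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", e)
        object.__setattr__(self, "stress", s)
        if e.shape != s.shape or e.ndim != 1:
            raise ValueError("strain and stress must be equal-length 1-d arrays")
        if e.size and (e.min() < 0 or e.max() >= 1):
            raise ValueError("strain must lie in [0, 1)")


@dataclass(frozen=True)
class LinearRegion:
    """A strain window [lo, hi] over which the response is treated as linear."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi < 1.0):
            raise ValueError("need 0 <= lo < hi < 1")


FIRST_LINEAR_REGION = LinearRegion(0.0375, 0.115)
SECOND_LINEAR_REGION = LinearRegion(0.225, 0.30)

#: default common displacement grid: 0 to 3 mm in 0.01 mm steps
DEFAULT_GRID = np.round(np.linspace(0.0, 3.0, 301), 10)


def regularize(raw: ForceDisplacementCurve, grid: np.ndarray) -> ForceDisplacementCurve:
    """Resample a raw curve onto ``grid`` by monotone piecewise-cubic
    interpolation of force against displacement.

    Duplicate raw displacements are collapsed by averaging their forces
    first.  The grid must lie inside the raw displacement range (no
    extrapolation).  With fewer than 4 distinct raw points the scheme falls
    back to linear interpolation (logged).
    """
    grid = np.asarray(grid, dtype=float)
    d, f = raw.displacement, raw.force
    du, inv = np.unique(d, return_inverse=True)
    if du.size < d.size:
        fsum = np.zeros_like(du)
        cnt = np.zeros_like(du)
        np.add.at(fsum, inv, f)
        np.add.at(cnt, inv, 1.0)
        f = fsum / cnt
        d = du
    if grid.size and (grid.min() < d.min() - 1e-12 or grid.max() > d.max() + 1e-12):
        raise ValueError("grid extends outside the raw displacement range")
    if d.size < 2:
        raise ValueError("need at least two distinct raw points")
    if d.size < 4:
        log.warning("only %d distinct points; falling back to linear interpolation", d.size)
        fg = np.interp(grid, d, f)
    else:
        fg = PchipInterpolator(d, f)(grid)
    return ForceDisplacementCurve(grid.copy(), fg)


def pointwise_mean(
    curves: list[ForceDisplacementCurve],
) -> tuple[ForceDisplacementCurve, ForceDisplacementCurve]:
    """Point-wise mean and sample-std curves of regularised curves.

    All curves must share one displacement grid.  The std uses ddof=1 and is
    zero when only one curve is given.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0].displacement
    for c in curves[1:]:
        if c.displacement.shape != grid.shape or not np.allclose(
            c.displacement, grid, rtol=0, atol=1e-12
        ):
            raise ValueError("curves are not on a shared displacement grid")
    F = np.vstack([c.force for c in curves])
    mean = F.mean(axis=0)
    std = F.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    return (
        ForceDisplacementCurve(grid.copy(), mean),
        ForceDisplacementCurve(grid.copy(), std),
    )


def to_stress_strain(
    curve: ForceDisplacementCurve, indenter_radius: float, thickness: float
) -> StressStrainCurve:
    """Apparent stress–strain: sigma = F / (pi a^2), eps = d / h."""
    a, h = float(indenter_radius), float(thickness)
    if a <= 0 or h <= 0:
        raise ValueError("indenter radius and thickness must be positive")
    if curve.displacement.size and curve.displacement.max() >= h:
        raise ValueError("displacement reaches the sample thickness")
    return StressStrainCurve(
        curve.displacement / h, curve.force / (np.pi * a**2)
    )


def linear_region_modulus(ss: StressStrainCurve, region: LinearRegion) -> float:
    """Apparent Young's modulus: OLS slope of stress on strain in a window."""
    m = (ss.strain >= region.lo) & (ss.strain <= region.hi)
    if m.sum() < 2:
        raise ValueError("fewer than 2 curve points inside the linear region")
    slope, _ = np.polyfit(ss.strain[m], ss.stress[m], 1)
    return float(slope)


def two_region_moduli(
    raw: ForceDisplacementCurve,
    indenter_radius: float = 2.5,
    thickness: float = 10.0,
    grid: np.ndarray | None = None,
    first: LinearRegion = FIRST_LINEAR_REGION,
    second: LinearRegion = SECOND_LINEAR_REGION,
) -> tuple[float, float]:
    """Regularise a raw curve and extract both linear-region moduli (N/mm^2)."""
    if grid is None:
        grid = DEFAULT_GRID
    grid = grid[grid <= raw.displacement.max() + 1e-12]
    ss = to_stress_strain(regularize(raw, grid), indenter_radius, thickness)
    return linear_region_modulus(ss, first), linear_region_modulus(ss, second)
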