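"""Drucker stability screening of incompressible hyperelastic parameter sets.

A material is Drucker stable when every stress increment does positive work
on the strain increment that caused it, i.e. when the tangent material
stiffness is positive definite.  For an incompressible material the
hydrostatic pressure is indeterminate, and the convenient gauge
``sigma3 = d(sigma3) = 0`` reduces the check to the 2x2 in-plane tangent
``D`` mapping ``(de1, de2)`` to ``(dsigma1, dsigma2)`` with
``de3 = -de1 - de2``.  Positive definiteness of the symmetrised 2x2 ``D``
is equivalent to ``trace(D) > 0 and det(D) > 0``.

The screen walks each of the three homogeneous deformation modes over a
nominal-strain grid (default -0.9 to 30 in steps of 0.01, i.e. stretches
0.1 to 31) and reports the first increment, if any, where positivity fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import DeformationMode, HyperelasticParams, biaxial_cauchy_stress

__all__ = ["StabilityReport", "ModeVerdict", "tangent_matrix", "tangent_matrices", "drucker_scan"]

#: relative log-strain step for the symmetric-difference tangent
_FD_STEP = 1e-6


def _base_stretches(mode: DeformationMode, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane base stretches (lam1, lam2) of a mode; lam3 = 1/(lam1*lam2)."""
    if mode is DeformationMode.UNIAXIAL:
        return lam, lam**-0.5
    if mode is DeformationMode.EQUIBIAXIAL:
        return lam, lam.copy()
    return lam, np.ones_like(lam)


def tangent_matrices(
    params: HyperelasticParams, mode: DeformationMode | str, eps: np.ndarray
) -> np.ndarray:
    """Symmetrised 2x2 tangent stiffness D at each nominal strain in ``eps``.

    The base state is the mode's incompressible stretch triple at
    ``lam = 1 + eps``; increments are applied as log strains
    (``lam -> lam*exp(±h)``), under which incompressibility reads exactly
    ``de3 = -de1 - de2``.  Differencing is symmetric with relative step 1e-6,
    and D is symmetrised before use.
    """
    mode = DeformationMode(mode)
    eps = np.atleast_1d(np.asarray(eps, dtype=float))
    lam = 1.0 + eps
    if np.any(lam <= 0):
        raise ValueError("nominal strain must exceed -1 (stretch must stay positive)")
    l1, l2 = _base_stretches(mode, lam)
    h = _FD_STEP
    ep, em = np.exp(h), np.exp(-h)

    s1p, s2p = biaxial_cauchy_stress(params, l1 * ep, l2)
    s1m, s2m = biaxial_cauchy_stress(params, l1 * em, l2)
    d11 = (s1p - s1m) / (2 * h)
    d21 = (s2p - s2m) / (2 * h)
    s1p, s2p = biaxial_cauchy_stress(params, l1, l2 * ep)
    s1m, s2m = biaxial_cauchy_stress(params, l1, l2 * em)
    d12 = (s1p - s1m) / (2 * h)
    d22 = (s2p - s2m) / (2 * h)

    D = np.empty(eps.shape + (2, 2))
    D[..., 0, 0] = d11
    D[..., 1, 1] = d22
    D[..., 0, 1] = D[..., 1, 0] = 0.5 * (d12 + d21)
    return D


def tangent_matrix(
    params: HyperelasticParams, mode: DeformationMode | str, eps: float
) -> np.ndarray:
    """2x2 tangent material stiffness at a single nominal strain."""
    return tangent_matrices(params, mode, np.asarray([eps]))[0]


@dataclass(frozen=True)
class ModeVerdict:
    mode: DeformationMode
    stable: bool
    first_unstable_strain: float | None


@dataclass(frozen=True)
class StabilityReport:
    """Per-mode Drucker verdicts over a scanned nominal-strain range."""

    verdicts: tuple[ModeVerdict, ...]
    scanned_range: tuple[float, float, float]  # (lo, hi, step)

    @property
    def overall_stable(self) -> bool:
        return all(v.stable for v in self.verdicts)

    def verdict_for(self, mode: DeformationMode | str) -> ModeVerdict:
        mode = DeformationMode(mode)
        return next(v for v in self.verdicts if v.mode is mode)


def drucker_scan(
    params: HyperelasticParams,
    modes: tuple[DeformationMode, ...] = tuple(DeformationMode),
    lo: float = -0.9,
    hi: float = 30.0,
    step: float = 0.01,
) -> StabilityReport:
    """Screen a parameter set for Drucker stability over the three modes.

    At every strain increment the criterion ``trace(D) > 0 and det(D) > 0``
    is applied to the symmetrised tangent; the first failing increment per
    mode is recorded as ``first_unstable_strain``.
    """
    if lo <= -1.0:
        raise ValueError("scan range must satisfy lo > -1")
    n = int(round((hi - lo) / step)) + 1
    eps = lo + step * np.arange(n)
    verdicts = []
    for mode in modes:
        D = tangent_matrices(params, mode, eps)
        tr = D[:, 0, 0] + D[:, 1, 1]
        det = D[:, 0, 0] * D[:, 1, 1] - D[:, 0, 1] * D[:, 1, 0]
        bad = (tr <= 0) | (det <= 0)
        if bad.any():
            first = float(eps[int(np.argmax(bad))])
            verdicts.append(ModeVerdict(DeformationMode(mode), False, first))
        else:
            verdicts.append(ModeVerdict(DeformationMode(mode), True, None))
    return StabilityReport(tuple(verdicts), (lo, hi, step))
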