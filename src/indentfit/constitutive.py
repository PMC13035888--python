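"""Incompressible hyperelastic strain-energy functions and their exact stress
responses under homogeneous principal-stretch deformations.

Two isotropic, fully incompressible (J = det F = 1) material laws are provided:

* **Yeoh** — ``psi = C1*(I1-3) + C2*(I1-3)**2 + C3*(I1-3)**3`` with
  ``I1 = lam1**2 + lam2**2 + lam3**2``.
* **Ogden (N = 3)** — ``psi = sum_i mu_i/alpha_i * (lam1**alpha_i +
  lam2**alpha_i + lam3**alpha_i - 3)``.

All coefficients carry units of N/mm^2 (= MPa); stretches are dimensionless.
The hydrostatic pressure that enforces incompressibility is eliminated
analytically in the homogeneous modes handled here, using the gauge
``sigma3 = 0`` (the lateral face is traction free); in the finite-element
module it is an independent field instead.

Compression is represented by stretches below one (``lam = 0.7`` is 30 %
nominal compression).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "HyperelasticParams",
    "DeformationMode",
    "PrincipalStretches",
    "stretches_for_mode",
    "strain_energy",
    "principal_cauchy_stress",
    "biaxial_cauchy_stress",
    "nominal_stress",
    "initial_shear_modulus",
    "ogden_classical_to_solver",
    "ogden_solver_to_classical",
    "read_params_json",
    "write_params_json",
]


class DeformationMode(str, Enum):
    """The three homogeneous deformation modes used for material screening."""

    UNIAXIAL = "uniaxial"
    EQUIBIAXIAL = "equibiaxial"
    PLANAR = "planar"


@dataclass(frozen=True)
class HyperelasticParams:
    """A material-law tag plus its coefficients.

    Parameters
    ----------
    model
        ``"yeoh"`` or ``"ogden3"``.
    C
        Yeoh coefficients ``(C1, C2, C3)`` in N/mm^2 (``model="yeoh"`` only).
    mu, alpha
        Ogden moduli (N/mm^2) and exponents (dimensionless), three each
        (``model="ogden3"`` only).

    Coefficients are deliberately unconstrained in sign: fitted soft-tissue
    sets routinely contain negative entries, and physical admissibility is
    screened separately (see :mod:`indentfit.stability`).
    """

    model: str
    C: tuple[float, float, float] | None = None
    mu: tuple[float, float, float] | None = None
    alpha: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.model == "yeoh":
            if self.C is None or len(self.C) != 3:
                raise ValueError("yeoh model requires exactly 3 coefficients C")
            object.__setattr__(self, "C", tuple(float(c) for c in self.C))
            if not np.all(np.isfinite(self.C)):
                raise ValueError("yeoh coefficients must be finite")
            if self.mu is not None or self.alpha is not None:
                raise ValueError("yeoh model takes no (mu, alpha)")
        elif self.model == "ogden3":
            if self.mu is None or self.alpha is None or len(self.mu) != 3 or len(self.alpha) != 3:
                raise ValueError("ogden3 model requires 3 (mu_i, alpha_i) pairs")
            object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
            object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
            if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.alpha))):
                raise ValueError("ogden3 coefficients must be finite")
            if self.C is not None:
                raise ValueError("ogden3 model takes no C")
        else:
            raise ValueError(f"unknown model {self.model!r}; expected 'yeoh' or 'ogden3'")

    # -- flat vector codec used by the optimiser ---------------------------
    def to_vector(self) -> np.ndarray:
        if self.model == "yeoh":
            return np.asarray(self.C, dtype=float)
        return np.asarray(
            [self.mu[0], self.alpha[0], self.mu[1], self.alpha[1], self.mu[2], self.alpha[2]],
            dtype=float,
        )

    @staticmethod
    def from_vector(model: str, x: np.ndarray) -> "HyperelasticParams":
        x = np.asarray(x, dtype=float)
        if model == "yeoh":
            return HyperelasticParams("yeoh", C=tuple(x))
        return HyperelasticParams("ogden3", mu=(x[0], x[2], x[4]), alpha=(x[1], x[3], x[5]))


@dataclass(frozen=True)
class PrincipalStretches:
    """An incompressible principal-stretch triple (unit product)."""

    lam1: float
    lam2: float
    lam3: float

    def __post_init__(self) -> None:
        lams = (self.lam1, self.lam2, self.lam3)
        if any(l <= 0 for l in lams):
            raise ValueError("principal stretches must be positive")
        if abs(self.lam1 * self.lam2 * self.lam3 - 1.0) > 1e-12:
            raise ValueError("stretches violate incompressibility (product != 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam1, self.lam2, self.lam3])


def stretches_for_mode(mode: DeformationMode | str, lam: float) -> PrincipalStretches:
    """Principal stretches of an incompressible homogeneous deformation.

    uniaxial   -> (lam, lam**-0.5, lam**-0.5)
    equibiaxial-> (lam, lam, lam**-2)
    planar     -> (lam, 1, 1/lam)    (pure shear)
    """
    lam = float(lam)
    if lam <= 0:
        raise ValueError("stretch must be positive")
    mode = DeformationMode(mode)
    if mode is DeformationMode.UNIAXIAL:
        t = lam**-0.5
        # renormalise so the product is exactly 1 in floating point
        return PrincipalStretches(lam, t, 1.0 / (lam * t))
    if mode is DeformationMode.EQUIBIAXIAL:
        return PrincipalStretches(lam, lam, 1.0 / lam**2)
    return PrincipalStretches(lam, 1.0, 1.0 / lam)


def _dpsi_dlam(params: HyperelasticParams, lams: np.ndarray) -> np.ndarray:
    """d(psi)/d(lam_i), elementwise over the last axis of ``lams``."""
    if params.model == "yeoh":
        c1, c2, c3 = params.C
        x = np.sum(lams**2, axis=-1, keepdims=True) - 3.0
        dpsi_dI1 = c1 + 2.0 * c2 * x + 3.0 * c3 * x**2
        return 2.0 * dpsi_dI1 * lams
    mu = np.asarray(params.mu)
    al = np.asarray(params.alpha)
    if np.any(al == 0.0):
        raise ValueError("ogden3 exponents alpha_i must be nonzero")
    # sum_k mu_k * lam**(alpha_k - 1), evaluated in log space for robustness
    loglam = np.log(lams)[..., None]
    return np.sum(mu * np.exp((al - 1.0) * loglam), axis=-1)


def strain_energy(params: HyperelasticParams, s: PrincipalStretches) -> float:
    """Strain-energy density (N/mm^2) at an incompressible stretch state."""
    lams = s.as_array()
    if params.model == "yeoh":
        c1, c2, c3 = params.C
        x = float(np.sum(lams**2)) - 3.0
        return c1 * x + c2 * x**2 + c3 * x**3
    mu = np.asarray(params.mu)
    al = np.asarray(params.alpha)
    if np.any(al == 0.0):
        raise ValueError("ogden3 exponents alpha_i must be nonzero")
    powers = np.exp(al[None, :] * np.log(lams)[:, None])  # lam_i ** alpha_k
    return float(np.sum(mu / al * (np.sum(powers, axis=0) - 3.0)))


def biaxial_cauchy_stress(
    params: HyperelasticParams, lam1: np.ndarray, lam2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane principal Cauchy stresses of a general incompressible biaxial
    state ``(lam1, lam2, lam3 = 1/(lam1*lam2))`` under the traction-free gauge
    ``sigma3 = 0``.

    ``sigma_i = lam_i * dpsi/dlam_i - p`` with ``p = lam3 * dpsi/dlam3``.
    Vectorised over arrays of stretches.
    """
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    lam3 = 1.0 / (lam1 * lam2)
    lams = np.stack(np.broadcast_arrays(lam1, lam2, lam3), axis=-1)
    d = _dpsi_dlam(params, lams)
    p = lams[..., 2] * d[..., 2]
    return lams[..., 0] * d[..., 0] - p, lams[..., 1] * d[..., 1] - p


def principal_cauchy_stress(
    params: HyperelasticParams, mode: DeformationMode | str, lam: float
) -> tuple[float, float]:
    """(sigma1, sigma2) in N/mm^2 along a homogeneous deformation mode.

    The pressure is fixed by ``sigma3 = 0``; in the uniaxial mode this also
    yields ``sigma2 = 0`` identically.
    """
    s = stretches_for_mode(mode, lam)
    s1, s2 = biaxial_cauchy_stress(params, s.lam1, s.lam2)
    return float(s1), float(s2)


def nominal_stress(params: HyperelasticParams, mode: DeformationMode | str, lam: float) -> float:
    """First Piola–Kirchhoff stress on the controlled axis, P1 = sigma1 / lam."""
    s1, _ = principal_cauchy_stress(params, mode, lam)
    return s1 / float(lam)


def initial_shear_modulus(params: HyperelasticParams) -> float:
    """Linearised (small-strain) shear modulus mu0, in N/mm^2.

    Yeoh: ``2*C1``.  Ogden in the mu_i/alpha_i form used here:
    ``sum(mu_i*alpha_i)/2``.  The incompressible Young's modulus is
    ``E0 = 3*mu0``.
    """
    if params.model == "yeoh":
        return 2.0 * params.C[0]
    return 0.5 * float(np.dot(params.mu, params.alpha))


def ogden_classical_to_solver(mu: np.ndarray, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert Ogden coefficients from the classical ``mu_i/alpha_i`` energy
    prefactor used throughout this package to the ``2*mu_i/alpha_i**2``
    convention common in commercial FE solvers (exponents are unchanged)."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    return mu * alpha / 2.0, alpha.copy()


def ogden_solver_to_classical(mu: np.ndarray, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`ogden_classical_to_solver`."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    return 2.0 * mu / alpha, alpha.copy()


# ---------------------------------------------------------------------------
# serialization — {"model": "yeoh", "units": "N_per_mm2", "C": [...]}
# ---------------------------------------------------------------------------

def write_params_json(params: HyperelasticParams, path: str | Path) -> None:
    """Serialise a parameter set; numbers survive round trips losslessly."""
    if params.model == "yeoh":
        obj = {"model": "yeoh", "units": "N_per_mm2", "C": list(params.C)}
    else:
        obj = {
            "model": "ogden3",
            "units": "N_per_mm2",
            "mu": list(params.mu),
            "alpha": list(params.alpha),
        }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_params_json(path: str | Path) -> HyperelasticParams:
    obj = json.loads(Path(path).read_text())
    model = obj.get("model")
    if model == "yeoh":
        return HyperelasticParams("yeoh", C=tuple(obj["C"]))
    if model == "ogden3":
        return HyperelasticParams("ogden3", mu=tuple(obj["mu"]), alpha=tuple(obj["alpha"]))
    raise ValueError(f"unknown model {model!r} in {path}")
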