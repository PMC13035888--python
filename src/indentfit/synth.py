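"""Synthetic indentation cohorts with realistic statistical structure.

No public dataset of per-specimen breast-tissue indentation curves exists,
so the pipeline is validated on synthetic cohorts that emulate the study
design it targets: 8 patients contributing 33 cylindrical specimens
(20 mm diameter, 10 mm height), each loaded by a 5 mm flat punch to 30 %
strain at 30 %/min and sampled at 100 Hz, with force quantisation coarse
relative to the displacement resolution.

Each specimen's ground-truth material is a group-level reference parameter
set (by default the published Yeoh sets for the two age subgroups) times a
patient-level and a specimen-level log-normal scale factor.  Because the
equilibrium equations are homogeneous in the stress scale, scaling the
coefficients scales the whole force curve identically, so every specimen
truth stays Drucker stable by construction and only two FE solves are
needed per cohort.  Measurement noise is multiplicative Gaussian on force
followed by quantisation to the load-cell step.

The generating truth is stored on each record (hidden from the pipeline)
so recovery experiments can validate calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constitutive import HyperelasticParams
from .curves import ForceDisplacementCurve
from .invfit import ForwardModel
from .reference import YEOH_GROUPS
from .stability import drucker_scan

__all__ = ["SpecimenRecord", "CohortConfig", "generate_specimen", "generate_cohort",
           "cohort_metadata"]


@dataclass(frozen=True)
class SpecimenRecord:
    """One synthetic specimen: metadata, measured curve, and hidden truth."""

    specimen_id: str
    patient_id: str
    age_years: float
    bmi_kg_m2: float
    menopause: str  # "pre" | "post"
    side: str  # "left" | "right"
    thickness_mm: float
    curve: ForceDisplacementCurve
    truth_params: HyperelasticParams
    truth_scale: float  # patient x specimen scale applied to the curve


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults reproduce the emulated study: 8 patients / 33 specimens,
    age-driven group truths from the published Yeoh sets, 20 % specimen-
    and 10 % patient-level stiffness dispersion (log-normal), 2 % relative
    force noise, 0.002 N force quantisation, and a 0-3 mm loading ramp
    over 60 s sampled at 100 Hz.
    """

    n_patients: int = 8
    n_specimens: int = 33
    group_truths: dict[str, HyperelasticParams] = field(
        default_factory=lambda: {
            "age_lt50": YEOH_GROUPS["age_lt50"],
            "age_gt50": YEOH_GROUPS["age_gt50"],
        }
    )
    sigma_specimen: float = 0.2  # log-normal sigma of the specimen scale
    sigma_patient: float = 0.1  # log-normal sigma of the patient scale
    sigma_force: float = 0.02  # relative Gaussian force noise
    quantization_N: float = 0.002  # load-cell force step
    ramp_mm: float = 3.0
    ramp_s: float = 60.0
    sample_hz: float = 100.0
    decimate: int = 1  # keep every k-th ramp sample
    thickness_mm: float = 10.0
    mesh_preset: str = "medium"
    n_steps: int = 30
    couple_menopause_to_age: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_specimen, self.sigma_patient, self.sigma_force) < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.quantization_N < 0:
            raise ValueError("quantization step must be non-negative")
        if self.n_specimens < self.n_patients:
            raise ValueError("need at least one specimen per patient")


def _ramp_grid(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(config.ramp_s * config.sample_hz))
    t = np.arange(n + 1) / config.sample_hz
    d = config.ramp_mm * t / config.ramp_s
    if config.decimate > 1:
        t, d = t[:: config.decimate], d[:: config.decimate]
    return t, d


def generate_specimen(
    truth: HyperelasticParams,
    scale: float,
    config: CohortConfig,
    rng: np.random.Generator,
    forward: ForwardModel,
    check_stability: bool = False,
) -> ForceDisplacementCurve:
    """Synthesise one measured curve from a ground-truth material.

    The noiseless base curve is the FE forward solution evaluated on the
    ramp grid (shape-preserving interpolation between load steps), scaled
    by ``scale``; then multiplicative force noise and quantisation are
    applied.  ``check_stability=True`` rejects Drucker-unstable truths.
    """
    if check_stability and not drucker_scan(truth).overall_stable:
        raise ValueError("generating truth is not Drucker stable")
    from scipy.interpolate import PchipInterpolator

    base = forward.curve(truth)
    t, d = _ramp_grid(config)
    f = scale * PchipInterpolator(base.displacement, base.force)(d)
    if config.sigma_force > 0:
        f = f * (1.0 + rng.normal(0.0, config.sigma_force, size=f.shape))
    if config.quantization_N > 0:
        f = np.round(f / config.quantization_N) * config.quantization_N
    return ForceDisplacementCurve(d, f, time=t)


def _allocate(n_items: int, n_bins: int) -> list[int]:
    base, extra = divmod(n_items, n_bins)
    return [base + (1 if i < extra else 0) for i in range(n_bins)]


def generate_cohort(
    config: CohortConfig | None = None, forward: ForwardModel | None = None
) -> list[SpecimenRecord]:
    """Generate a reproducible synthetic cohort.

    Patients split into a younger (age < 50, premenopausal) and an older
    (age > 50, postmenopausal by default coupling) stratum in roughly the
    3:5 ratio of the emulated study; each stratum draws its specimens'
    ground truth from the corresponding entry of ``group_truths``.  BMI is
    drawn around the overweight threshold so both BMI subgroups are
    populated; breast side is assigned per specimen.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if forward is None:
        # pass a shared ForwardModel across cohorts to reuse its solve cache
        forward = ForwardModel(
            preset=config.mesh_preset, delta_max=config.ramp_mm, n_steps=config.n_steps
        )

    n_old = max(1, round(config.n_patients * 3 / 8))
    n_young = config.n_patients - n_old
    ages = np.concatenate([
        rng.uniform(34.0, 49.0, size=n_young),
        rng.uniform(51.0, 68.0, size=n_old),
    ])
    # BMI straddles the threshold; flip one patient if a side came up empty
    bmi = rng.uniform(20.5, 31.0, size=config.n_patients)
    if np.all(bmi >= 25.0):
        bmi[0] = 23.0
    if np.all(bmi < 25.0):
        bmi[0] = 27.0
    patient_scale = np.exp(rng.normal(0.0, config.sigma_patient, size=config.n_patients))

    # specimens per patient: older stratum contributes proportionally more,
    # mirroring the 14/19 split of the emulated study
    n_spec_old = round(config.n_specimens * 14 / 33)
    counts = _allocate(config.n_specimens - n_spec_old, n_young) + _allocate(
        n_spec_old, n_old
    )

    records: list[SpecimenRecord] = []
    spec_no = 0
    for ip in range(config.n_patients):
        age = float(ages[ip])
        group = "age_lt50" if age < 50.0 else "age_gt50"
        menopause = ("post" if age >= 50.0 else "pre") if config.couple_menopause_to_age \
            else ("post" if rng.random() < 0.4 else "pre")
        truth = config.group_truths[group]
        for _ in range(counts[ip]):
            spec_no += 1
            s = float(patient_scale[ip] * np.exp(rng.normal(0.0, config.sigma_specimen)))
            side = "right" if rng.random() < 2 / 3 else "left"
            curve = generate_specimen(truth, s, config, rng, forward)
            records.append(
                SpecimenRecord(
                    specimen_id=f"S{spec_no:03d}",
                    patient_id=f"P{ip + 1:02d}",
                    age_years=round(age, 1),
                    bmi_kg_m2=round(float(bmi[ip]), 1),
                    menopause=menopause,
                    side=side,
                    thickness_mm=config.thickness_mm,
                    curve=curve,
                    truth_params=truth,
                    truth_scale=s,
                )
            )
    # both sides must be represented
    sides = {r.side for r in records}
    if len(sides) == 1:
        records[0] = replace(records[0], side="left" if "right" in sides else "right")
    return records


def cohort_metadata(records: list[SpecimenRecord]) -> pd.DataFrame:
    """Tidy metadata table (one row per specimen, no curves, no truths)."""
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "age_years": [r.age_years for r in records],
            "bmi_kg_m2": [r.bmi_kg_m2 for r in records],
            "menopause": [r.menopause for r in records],
            "side": [r.side for r in records],
            "thickness_mm": [r.thickness_mm for r in records],
        }
    )
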