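"""Readers and writers for the pipeline's plain-text formats.

* curve CSV — header exactly ``time_s,displacement_mm,force_N``; the time
  column may be empty.  Displacement must be strictly non-decreasing and
  start at 0 or later; violations are reported with their row number.
* parameter JSON — see :mod:`indentfit.constitutive`.
* metadata CSV — one row per specimen.
* YAML pipeline configuration with strict key validation.

Numbers are written with 17 significant digits so round trips are
bit-lossless.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import ForceDisplacementCurve

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "write_metadata_csv",
    "read_metadata_csv",
    "PipelineConfig",
    "read_config",
    "config_hash",
]

_CURVE_HEADER = ["time_s", "displacement_mm", "force_N"]


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def write_curve_csv(curve: ForceDisplacementCurve, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CURVE_HEADER)
        t = curve.time
        for i in range(len(curve)):
            w.writerow(
                ["" if t is None else _fmt(t[i]), _fmt(curve.displacement[i]), _fmt(curve.force[i])]
            )


def read_curve_csv(path: str | Path) -> ForceDisplacementCurve:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != _CURVE_HEADER:
        raise ValueError(f"{path}: bad header; expected {','.join(_CURVE_HEADER)!r}")
    time, disp, force = [], [], []
    has_time = True
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != 3:
            raise ValueError(f"{path}: row {i}: expected 3 columns")
        try:
            if row[0].strip() == "":
                has_time = False
            else:
                time.append(float(row[0]))
            disp.append(float(row[1]))
            force.append(float(row[2]))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: non-numeric cell") from exc
    d = np.asarray(disp)
    if d.size > 1 and np.any(np.diff(d) < 0):
        bad = int(np.argmax(np.diff(d) < 0)) + 3  # +2 header/1-based, +1 second row
        raise ValueError(f"{path}: row {bad}: displacement decreases")
    t = np.asarray(time) if has_time and len(time) == len(disp) else None
    return ForceDisplacementCurve(d, np.asarray(force), time=t)


_META_COLUMNS = [
    "specimen_id", "patient_id", "age_years", "bmi_kg_m2", "menopause", "side",
    "thickness_mm",
]


def write_metadata_csv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False, columns=_META_COLUMNS, float_format="%.17g")


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (strict: unknown keys rejected)."""

    seed: int = 0
    mesh_preset: str = "medium"
    fit_mesh_preset: str = "coarse"
    model: str = "yeoh"
    first_region: tuple[float, float] = (0.0375, 0.115)
    second_region: tuple[float, float] = (0.225, 0.30)
    tol_x: float = 1e-4
    tol_f: float = 1e-12
    max_iter: int = 2000
    alpha: float = 0.05
    force_signed_rank: bool = False
    n_patients: int = 8
    n_specimens: int = 33
    sigma_specimen: float = 0.2
    sigma_patient: float = 0.1
    sigma_force: float = 0.02
    quantization_N: float = 0.002
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mesh_preset not in ("coarse", "medium", "fine") or self.fit_mesh_preset not in (
            "coarse", "medium", "fine",
        ):
            raise ValueError("mesh presets must be coarse|medium|fine")
        if self.model not in ("yeoh", "ogden3"):
            raise ValueError("model must be yeoh or ogden3")
        for region in (self.first_region, self.second_region):
            lo, hi = region
            if not (0 <= lo < hi < 1):
                raise ValueError(f"invalid linear region {region}")


def read_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            raise ValueError(f"{path}: unknown configuration key {key!r}")
    for tup in ("first_region", "second_region"):
        if tup in raw and isinstance(raw[tup], list):
            raw[tup] = tuple(raw[tup])
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash identifying a configuration (embedded in outputs)."""
    blob = json.dumps(
        {k: getattr(config, k) for k in sorted(PipelineConfig.__dataclass_fields__)},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
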