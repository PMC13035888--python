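"""Published reference parameter sets for human breast tissue.

Yeoh and Ogden (N = 3) coefficients identified by inverse finite-element
analysis of flat-punch indentation of ex vivo breast tissue, one set per
population subgroup (age threshold 50 years, BMI threshold 25 kg/m^2,
menopausal status, breast side).  Units are N/mm^2 throughout; the Ogden
sets follow the classical ``mu_i/alpha_i`` energy prefactor convention of
:mod:`indentfit.constitutive`.

Also included are the corresponding apparent Young's moduli (mean, sample
std, n) per subgroup for the two linear strain regions of the indentation
stress–strain curve; these anchor the effect sizes that the synthetic
cohort generator emulates.
"""

from __future__ import annotations

from .constitutive import HyperelasticParams, ogden_solver_to_classical

__all__ = [
    "GROUP_LABELS",
    "YEOH_GROUPS",
    "OGDEN3_GROUPS",
    "ALL_REFERENCE_PARAMS",
    "YOUNGS_MODULUS_GROUPS",
]

#: subgroup labels, keyed by partitioning factor
GROUP_LABELS: dict[str, tuple[str, str]] = {
    "age": ("age_gt50", "age_lt50"),
    "bmi": ("bmi_gt25", "bmi_lt25"),
    "menopause": ("post_m", "pre_m"),
    "side": ("right", "left"),
}

_YEOH_RAW = {  # C1, C2, C3 in 1e-6 N/mm^2
    "age_gt50": (799.14, 1726.42, 5143.47),
    "age_lt50": (1200.00, 2000.00, 4000.00),
    "bmi_gt25": (1333.33, 1137.78, 2568.89),
    "bmi_lt25": (890.00, 2200.00, 5800.00),
    "post_m": (889.00, 900.00, 3900.00),
    "pre_m": (1200.00, 2000.00, 4000.00),
    "right": (938.19, 2168.35, 5701.17),
    "left": (1200.00, 2222.22, 829.44),
}

_OGDEN_RAW = {  # (mu_i in 1e-6 N/mm^2, alpha_i), quoted in the FE-solver convention
    "age_gt50": ((-21537.81, 2.15), (18911.25, 4.98), (4307.56, -4.85)),
    "age_lt50": ((-21598.50, 2.21), (20042.47, 4.26), (4003.58, -5.26)),
    "bmi_gt25": ((-20720.62, 2.07), (19459.53, 4.09), (3988.57, -3.87)),
    "bmi_lt25": ((-21827.24, 2.13), (19455.05, 5.40), (4025.95, -6.11)),
    "post_m": ((-23527.78, 2.04), (21027.78, 3.97), (4083.33, -4.39)),
    "pre_m": ((-21598.50, 2.21), (20042.47, 4.26), (4003.58, -5.26)),
    "right": ((-26326.21, 2.92), (21570.90, 5.62), (6165.84, -4.40)),
    "left": ((-20720.37, 2.07), (19459.72, 4.08), (3988.52, -3.87)),
}

YEOH_GROUPS: dict[str, HyperelasticParams] = {
    k: HyperelasticParams("yeoh", C=tuple(c * 1e-6 for c in v)) for k, v in _YEOH_RAW.items()
}

def _ogden_from_solver_row(row) -> HyperelasticParams:
    mu_s = [m * 1e-6 for m, _ in row]
    al = [a for _, a in row]
    mu_c, al_c = ogden_solver_to_classical(mu_s, al)
    return HyperelasticParams("ogden3", mu=tuple(mu_c), alpha=tuple(al_c))


#: Ogden sets converted to the classical ``mu_i/alpha_i`` convention used by
#: :mod:`indentfit.constitutive`.  The published rows follow the commercial
#: FE-solver convention (``2*mu_i/alpha_i**2`` energy prefactor): only under
#: that reading are all eight sets Drucker stable over the full screened
#: strain range, as the identification study they come from requires.
OGDEN3_GROUPS: dict[str, HyperelasticParams] = {
    k: _ogden_from_solver_row(v) for k, v in _OGDEN_RAW.items()
}

#: all 16 reference sets, keyed "yeoh:<group>" / "ogden3:<group>"
ALL_REFERENCE_PARAMS: dict[str, HyperelasticParams] = {
    **{f"yeoh:{k}": v for k, v in YEOH_GROUPS.items()},
    **{f"ogden3:{k}": v for k, v in OGDEN3_GROUPS.items()},
}

#: apparent Young's modulus (mean_1e-3_MPa, std, n) per subgroup and region
YOUNGS_MODULUS_GROUPS: dict[str, dict[str, tuple[float, float, int]]] = {
    "first": {
        "age_gt50": (9.35, 1.48, 14),
        "age_lt50": (13.07, 1.08, 19),
        "bmi_gt25": (12.07, 1.29, 16),
        "bmi_lt25": (10.95, 1.35, 17),
        "post_m": (6.88, 1.80, 9),
        "pre_m": (13.07, 1.08, 19),
        "right": (11.64, 1.10, 22),
        "left": (11.20, 1.79, 11),
    },
    "second": {
        "age_gt50": (42.17, 7.18, 14),
        "age_lt50": (44.28, 8.65, 19),
        "bmi_gt25": (32.67, 7.09, 16),
        "bmi_lt25": (53.47, 8.44, 17),
        "post_m": (32.85, 8.87, 9),
        "pre_m": (44.28, 8.65, 19),
        "right": (51.09, 7.83, 22),
        "left": (27.98, 4.99, 11),
    },
}
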