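"""Constitutive layer: kinematics, energies, stresses, serialization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indentfit.constitutive import (
    DeformationMode,
    HyperelasticParams,
    PrincipalStretches,
    initial_shear_modulus,
    nominal_stress,
    ogden_classical_to_solver,
    ogden_solver_to_classical,
    principal_cauchy_stress,
    read_params_json,
    strain_energy,
    stretches_for_mode,
    write_params_json,
)
from indentfit.reference import ALL_REFERENCE_PARAMS, OGDEN3_GROUPS, YEOH_GROUPS

MODES = list(DeformationMode)
YEOH_YOUNG = YEOH_GROUPS["age_lt50"]  # C = (1200, 2000, 4000) x 1e-6 N/mm^2


class TestKinematics:
    @pytest.mark.parametrize(
        "mode, lam, expected",
        [
            ("uniaxial", 1.0, (1.0, 1.0, 1.0)),
            ("planar", 2.0, (2.0, 1.0, 0.5)),
            ("equibiaxial", 1.1, (1.1, 1.1, 1.1**-2)),
        ],
    )
    def test_mode_stretches(self, mode, lam, expected):
        s = stretches_for_mode(mode, lam)
        assert s.as_array() == pytest.approx(expected, rel=1e-14)

    @given(st.sampled_from(MODES), st.floats(0.05, 20.0))
    @settings(max_examples=200, deadline=None)
    def test_unit_volume_product(self, mode, lam):
        s = stretches_for_mode(mode, lam)
        assert abs(s.lam1 * s.lam2 * s.lam3 - 1.0) < 1e-12

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            stretches_for_mode("uniaxial", 0.0)


class TestParams:
    def test_arity_enforced(self):
        with pytest.raises(ValueError):
            HyperelasticParams("yeoh", C=(1.0, 2.0))
        with pytest.raises(ValueError):
            HyperelasticParams("ogden3", mu=(1.0, 2.0), alpha=(1.0, 2.0))
        with pytest.raises(ValueError):
            HyperelasticParams("mooney", C=(1.0, 2.0, 3.0))

    def test_json_roundtrip_lossless(self, tmp_path):
        p = HyperelasticParams("yeoh", C=(1.2345678901234567e-3, -2e-3, 4.1e-3))
        f = tmp_path / "p.json"
        write_params_json(p, f)
        assert json.loads(f.read_text())["units"] == "N_per_mm2"
        q = read_params_json(f)
        assert q.C == p.C  # exact, 17 significant digits
        o = OGDEN3_GROUPS["right"]
        write_params_json(o, f)
        q = read_params_json(f)
        assert q.mu == o.mu and q.alpha == o.alpha


class TestEnergyAndStress:
    def test_reference_state_energy_zero(self, rng):
        ident = stretches_for_mode("uniaxial", 1.0)
        for p in ALL_REFERENCE_PARAMS.values():
            assert strain_energy(p, ident) == pytest.approx(0.0, abs=1e-18)
            s1, s2 = principal_cauchy_stress(p, "uniaxial", 1.0)
            assert abs(s1) < 1e-15 and abs(s2) < 1e-15

    def test_yeoh_energy_value(self):
        # direct substitution: I1 - 3 = 1.1^2 + 2/1.1 - 3
        s = stretches_for_mode("uniaxial", 1.1)
        x = 1.1**2 + 2.0 / 1.1 - 3.0
        c1, c2, c3 = YEOH_YOUNG.C
        expected = c1 * x + c2 * x**2 + c3 * x**3
        assert strain_energy(YEOH_YOUNG, s) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(3.5496e-5, rel=1e-4)

    def test_ogden_neo_hookean_reduction(self):
        mu0 = 2e-3
        og = HyperelasticParams("ogden3", mu=(mu0, 0.0, 0.0), alpha=(2.0, 1.0, 1.0))
        nh = HyperelasticParams("yeoh", C=(mu0 / 2, 0.0, 0.0))
        for lam in (0.6, 0.9, 1.3, 2.0):
            for mode in MODES:
                s = stretches_for_mode(mode, lam)
                assert strain_energy(og, s) == pytest.approx(strain_energy(nh, s), rel=1e-13)
                assert principal_cauchy_stress(og, mode, lam) == pytest.approx(
                    principal_cauchy_stress(nh, mode, lam), rel=1e-12, abs=1e-18
                )

    def test_yeoh_uniaxial_closed_form(self):
        # sigma1 = 2 (lam^2 - 1/lam) (C1 + 2 C2 x + 3 C3 x^2)
        for lam in (0.7, 0.9, 1.2):
            x = lam**2 + 2.0 / lam - 3.0
            c1, c2, c3 = YEOH_YOUNG.C
            expected = 2 * (lam**2 - 1 / lam) * (c1 + 2 * c2 * x + 3 * c3 * x**2)
            s1, s2 = principal_cauchy_stress(YEOH_YOUNG, "uniaxial", lam)
            assert s1 == pytest.approx(expected, rel=1e-13)
            assert abs(s2) < 1e-15 * max(1.0, abs(s1))
        assert principal_cauchy_stress(YEOH_YOUNG, "uniaxial", 0.7)[0] == pytest.approx(
            -7.5737e-3, rel=1e-4
        )

    def test_nominal_stress(self):
        P1 = nominal_stress(YEOH_YOUNG, "uniaxial", 0.9)
        s1, _ = principal_cauchy_stress(YEOH_YOUNG, "uniaxial", 0.9)
        assert P1 == pytest.approx(s1 / 0.9, rel=1e-14)
        assert P1 == pytest.approx(-8.975e-4, rel=1e-3)
        assert nominal_stress(YEOH_YOUNG, "uniaxial", 1.0) == pytest.approx(0.0, abs=1e-16)

    def test_ogden_zero_alpha_rejected(self):
        p = HyperelasticParams("ogden3", mu=(1e-3, 1e-3, 1e-3), alpha=(2.0, 0.0, -2.0))
        with pytest.raises(ValueError):
            strain_energy(p, stretches_for_mode("uniaxial", 1.1))

    def test_stress_matches_energy_gradient(self, rng):
        """Central-difference differentiation of the energy is the stress
        oracle (smaller sample than the acceptance sweep)."""
        h = 1e-6
        for _ in range(20):
            if rng.random() < 0.5:
                p = HyperelasticParams("yeoh", C=tuple(rng.uniform(-2e-3, 5e-3, 3)))
            else:
                p = HyperelasticParams(
                    "ogden3",
                    mu=tuple(rng.uniform(-5e-3, 5e-3, 3)),
                    alpha=tuple(rng.uniform(0.5, 5.0, 3) * rng.choice([-1, 1], 3)),
                )
            for mode in MODES:
                lam = rng.uniform(0.5, 2.0)
                s1, _ = principal_cauchy_stress(p, mode, lam)
                # sigma1 = d(psi)/d(log lam1) at fixed lam2 under J = 1
                base = stretches_for_mode(mode, lam)

                def psi(l1, l2):
                    return strain_energy(p, PrincipalStretches(l1, l2, 1.0 / (l1 * l2)))

                num = (
                    psi(base.lam1 * np.exp(h), base.lam2)
                    - psi(base.lam1 * np.exp(-h), base.lam2)
                ) / (2 * h)
                scale = max(abs(s1), 1e-8)
                assert num == pytest.approx(s1, rel=1e-5, abs=1e-6 * scale)


class TestShearModulus:
    def test_yeoh_mu0(self):
        assert initial_shear_modulus(YEOH_YOUNG) == pytest.approx(2.4e-3, rel=1e-12)

    def test_ogden_mu0_printed_row(self):
        # the published age>50 row, read literally in the classical form
        row = HyperelasticParams(
            "ogden3",
            mu=(-21537.81e-6, 18911.25e-6, 4307.56e-6),
            alpha=(2.15, 4.98, -4.85),
        )
        assert initial_shear_modulus(row) == pytest.approx(1.349e-2, rel=1e-3)

    def test_neo_hookean_equivalence(self):
        c1 = 1.7e-3
        y = HyperelasticParams("yeoh", C=(c1, 0, 0))
        o = HyperelasticParams("ogden3", mu=(2 * c1, 0, 0), alpha=(2.0, 1.0, 1.0))
        assert initial_shear_modulus(y) == pytest.approx(initial_shear_modulus(o), rel=1e-14)

    def test_all_reference_rows_positive_mu0_both_conventions(self):
        for p in YEOH_GROUPS.values():
            assert initial_shear_modulus(p) > 0
        for p in OGDEN3_GROUPS.values():
            assert initial_shear_modulus(p) > 0  # classical form
            mu_s, al = ogden_classical_to_solver(p.mu, p.alpha)
            assert mu_s.sum() > 0  # solver form: mu0 = sum(mu_i)

    def test_convention_conversion_roundtrip(self, rng):
        mu = rng.uniform(-1e-2, 1e-2, 3)
        al = rng.uniform(0.5, 6.0, 3)
        mu2, al2 = ogden_solver_to_classical(*ogden_classical_to_solver(mu, al))
        np.testing.assert_allclose(mu2, mu, rtol=1e-15)
        np.testing.assert_allclose(al2, al, rtol=0)
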