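"""Structural model: covariate map, %CV transform, analytic solution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poptk.pkmodel import (
    DoseEvent,
    StructuralParams,
    ThetaVector,
    auc,
    compartment_amounts,
    cv_percent,
    individual_params,
    omega_sq_from_cv,
    predict_conc,
    predict_conc_ode,
    terminal_half_life,
)

from conftest import STUDY_DOSE, TABLE_PARAMS

THETA = ThetaVector(1.31, 9.84, 197.0, 39.1, 0.6, 9.01, 1.63)


class TestIndividualParams:
    def test_reference_subject(self):
        p = individual_params(THETA, wt=70, inducer=0)
        assert p.cl == pytest.approx(1.31)
        assert p.v1 == pytest.approx(9.84)

    def test_inducer_multiplies_clearance(self):
        p = individual_params(THETA, wt=70, inducer=1)
        assert p.cl == pytest.approx(1.31 * 1.63)  # 2.1353
        assert p.v1 == pytest.approx(9.84)  # volumes untouched

    def test_allometric_scaling_at_double_weight(self):
        p = individual_params(THETA, wt=140, inducer=0)
        assert p.cl == pytest.approx(1.31 * 2**0.75)  # ~2.2031
        assert p.v1 == pytest.approx(19.68)
        assert p.q2 == pytest.approx(197.0 * 2**0.75)

    def test_eta_enters_exponentially(self):
        p = individual_params(THETA, 70, 0, eta=(0.1, -0.2, 0.3))
        assert p.cl == pytest.approx(1.31 * np.exp(0.1))
        assert p.v1 == pytest.approx(9.84 * np.exp(-0.2))
        assert p.v2 == pytest.approx(39.1 * np.exp(0.3))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            individual_params(THETA, -1.0, 0)


class TestCvTransform:
    @pytest.mark.parametrize(
        "om2,cv",
        [(0.0, 0.0), (0.1064, 33.54), (0.0322, 18.09), (0.0366, 19.31)],
    )
    def test_reference_values(self, om2, cv):
        assert cv_percent(om2) == pytest.approx(cv, abs=0.05)

    @given(om2=st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, om2):
        assert omega_sq_from_cv(cv_percent(om2)) == pytest.approx(om2, abs=1e-12)

    def test_monotone(self):
        grid = np.linspace(0, 2, 50)
        assert np.all(np.diff(cv_percent(grid)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(-0.1)


class TestPredictConc:
    def test_zero_before_and_at_infusion_start(self):
        c = predict_conc(TABLE_PARAMS, STUDY_DOSE, [0.0])
        assert c[0] == 0.0

    def test_linearity_in_dose(self):
        t = np.array([0.1, 0.5, 2.0, 24.0, 96.0])
        c1 = predict_conc(TABLE_PARAMS, STUDY_DOSE, t)
        c2 = predict_conc(TABLE_PARAMS, [DoseEvent(0.0, 1 / 6, 50.0)], t)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_superposition_of_two_doses(self):
        t = np.linspace(0.0, 48.0, 50)
        one = predict_conc(TABLE_PARAMS, [DoseEvent(0, 1 / 6, 25)], t)
        shifted = predict_conc(TABLE_PARAMS, [DoseEvent(12, 1 / 6, 25)], t)
        both = predict_conc(
            TABLE_PARAMS, [DoseEvent(0, 1 / 6, 25), DoseEvent(12, 1 / 6, 25)], t
        )
        np.testing.assert_allclose(both, one + shifted, rtol=1e-10)

    def test_matches_stiff_ode_at_reference_parameters(self):
        t = np.array([0.25, 2.0, 24.0, 96.0])
        ca = predict_conc(TABLE_PARAMS, STUDY_DOSE, t)
        co = predict_conc_ode(TABLE_PARAMS, STUDY_DOSE, t)
        np.testing.assert_allclose(ca, co, rtol=1e-8)

    def test_monotone_nondecreasing_during_infusion(self):
        t = np.linspace(0.0, 1.0 / 6.0, 40)
        c = predict_conc(TABLE_PARAMS, STUDY_DOSE, t)
        assert np.all(np.diff(c) >= -1e-12)

    def test_mass_balance_without_elimination(self):
        p = StructuralParams(cl=0.0, v1=9.84, q2=197.0, v2=39.1, q3=0.6, v3=9.01)
        amts = compartment_amounts(p, STUDY_DOSE, [0.5, 10.0, 96.0])
        np.testing.assert_allclose(amts.sum(axis=1), 25.0, rtol=1e-10)

    @pytest.mark.parametrize("ncomp", [1, 2, 3])
    def test_initial_slope_consistent_across_structures(self, ncomp):
        # immediately after infusion start the concentration is dominated by
        # input into V1, independent of the peripheral structure
        c = predict_conc(TABLE_PARAMS, STUDY_DOSE, [1e-5], ncomp=ncomp)
        rate = 150.0  # mg/h
        assert c[0] == pytest.approx(rate * 1e-5 / 9.84, rel=1e-2)


class TestHalfLifeAndAuc:
    def test_one_compartment_degenerate(self):
        p = StructuralParams(cl=1.31, v1=9.84, q2=0.0, v2=1.0, q3=0.0, v3=1.0)
        assert terminal_half_life(p) == pytest.approx(np.log(2) * 9.84 / 1.31, rel=1e-9)

    def test_dimensional_invariance(self):
        t0 = terminal_half_life(TABLE_PARAMS)
        scaled = StructuralParams(
            cl=1.31 * 3, v1=9.84 * 3, q2=197 * 3, v2=39.1 * 3, q3=0.6 * 3, v3=9.01 * 3
        )
        assert terminal_half_life(scaled) == pytest.approx(t0, rel=1e-10)

    def test_matches_characteristic_polynomial_root(self):
        # smallest root of the characteristic cubic, found independently
        p = TABLE_PARAMS
        k10, k12, k21 = p.cl / p.v1, p.q2 / p.v1, p.q2 / p.v2
        k13, k31 = p.q3 / p.v1, p.q3 / p.v3
        coeffs = [
            1.0,
            -(k10 + k12 + k21 + k13 + k31),
            k10 * k21 + k10 * k31 + k12 * k31 + k13 * k21 + k21 * k31,
            -k10 * k21 * k31,
        ]
        lam_z = min(abs(r) for r in np.roots(coeffs))
        assert terminal_half_life(p) == pytest.approx(np.log(2) / lam_z, rel=1e-9)

    def test_auc_infinity_is_dose_over_cl(self):
        assert auc(TABLE_PARAMS, STUDY_DOSE) == pytest.approx(25.0 / 1.31, rel=1e-12)

    def test_partial_auc_matches_fine_trapezoid(self):
        t = np.linspace(0, 96, 200001)
        c = predict_conc(TABLE_PARAMS, STUDY_DOSE, t)
        assert auc(TABLE_PARAMS, STUDY_DOSE, 96.0) == pytest.approx(
            np.trapezoid(c, t), rel=1e-6
        )


class TestAnalyticVsOdeRandomDraws:
    def test_agreement_over_random_parameter_sets(self):
        """Log-uniform draws 10x around the reference values, all times."""
        rng = np.random.default_rng(2024)
        t = np.array([1 / 12, 0.25, 1.0, 6.0, 24.0, 96.0])
        worst = 0.0
        for _ in range(30):
            vals = {
                k: getattr(TABLE_PARAMS, k) * 10 ** rng.uniform(-1, 1)
                for k in ("cl", "v1", "q2", "v2", "q3", "v3")
            }
            p = StructuralParams(**vals)
            ca = predict_conc(p, STUDY_DOSE, t)
            co = predict_conc_ode(p, STUDY_DOSE, t, rtol=1e-11, atol=1e-14)
            floor = 1e-9 * co.max()  # below this the ODE oracle itself drifts
            rel = np.abs(ca - co) / np.maximum(np.abs(co), floor)
            worst = max(worst, rel.max())
        assert worst < 1e-6
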