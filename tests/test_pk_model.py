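"""Structural model: covariate equations, kinetics, steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import steady_state_by_superposition
from popkarc import (
    CovariateEffect,
    DoseEvent,
    IndividualParams,
    PopulationModel,
    Regimen,
    concentration,
    individual_params,
    steady_state_interval,
    typical_params,
)

PARAMS = IndividualParams(cl=2.20, v=3.36)
SINGLE_DOSE = [DoseEvent(0.0, 500.0, 0.5)]


class TestTypicalParams:
    @pytest.mark.parametrize(
        "weight,age,cl,v",
        [
            (10.25, 1.25, 2.20, 3.36),  # reference covariates: identity
            (8.0, 1.25, 1.827, 2.622),
            (10.25, 0.35, 0.947, None),
        ],
    )
    def test_final_model_equations(self, ref_model, weight, age, cl, v):
        p = typical_params(weight, age, ref_model)
        assert p.cl == pytest.approx(cl, abs=5e-4)
        if v is not None:
            assert p.v == pytest.approx(v, abs=5e-4)

    def test_reference_identity_is_exact(self, ref_model):
        p = typical_params(ref_model.ref_weight, ref_model.ref_age, ref_model)
        assert p.cl == ref_model.theta1
        assert p.v == ref_model.theta2

    def test_nonpositive_covariates_rejected(self, ref_model):
        with pytest.raises(ValueError):
            typical_params(-1.0, 1.0, ref_model)
        with pytest.raises(ValueError):
            typical_params(10.0, 0.0, ref_model)

    @given(
        w1=st.floats(5.0, 20.0),
        w2=st.floats(5.0, 20.0),
        a1=st.floats(0.2, 2.0),
        a2=st.floats(0.2, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_weight_and_age(self, ref_model, w1, w2, a1, a2):
        if w1 > w2:
            w1, w2 = w2, w1
        if a1 > a2:
            a1, a2 = a2, a1
        lo = typical_params(w1, a1, ref_model)
        hi_w = typical_params(w2, a1, ref_model)
        hi_a = typical_params(w1, a2, ref_model)
        assert hi_w.cl >= lo.cl and hi_w.v >= lo.v
        assert hi_a.cl >= lo.cl  # age acts on CL only (positive exponent)
        assert hi_a.v == pytest.approx(lo.v)

    def test_extra_effect_factors(self, ref_model):
        from dataclasses import replace

        eff = CovariateEffect("sex", "v", "proportional", coefficient=0.2)
        m = replace(ref_model, extra_effects=(eff,))
        p0 = typical_params(10.25, 1.25, m, covariates={"sex": 0.0})
        p1 = typical_params(10.25, 1.25, m, covariates={"sex": 1.0})
        assert p1.v == pytest.approx(1.2 * p0.v)
        assert p1.cl == pytest.approx(p0.cl)


class TestIndividualParams:
    def test_zero_eta_is_identity(self):
        p = individual_params(PARAMS, 0.0, 0.0)
        assert (p.cl, p.v) == (PARAMS.cl, PARAMS.v)

    def test_exponential_law(self):
        p = individual_params(PARAMS, np.log(2.0), 0.0)
        assert p.cl == pytest.approx(2 * PARAMS.cl)
        assert p.v == pytest.approx(PARAMS.v)

    def test_group_composition(self):
        down = individual_params(PARAMS, -np.log(2.0), 0.3)
        back = individual_params(down, np.log(2.0), -0.3)
        assert back.cl == pytest.approx(PARAMS.cl)
        assert back.v == pytest.approx(PARAMS.v)

    def test_ke_is_cl_over_v(self):
        assert PARAMS.ke == PARAMS.cl / PARAMS.v


class TestConcentration:
    def test_causality(self):
        assert concentration(-0.1, SINGLE_DOSE, PARAMS) == 0.0
        assert concentration(0.0, SINGLE_DOSE, PARAMS) == 0.0

    def test_end_of_infusion_value(self):
        assert concentration(0.5, SINGLE_DOSE, PARAMS) == pytest.approx(
            126.9, abs=0.05
        )

    def test_washout_value(self):
        assert concentration(2.5, SINGLE_DOSE, PARAMS) == pytest.approx(34.3, abs=0.05)

    @given(scale=st.floats(0.1, 10.0), t=st.floats(0.1, 24.0))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_dose(self, scale, t):
        doses = [DoseEvent(0.0, 500.0, 0.5), DoseEvent(12.0, 500.0, 0.5)]
        scaled = [DoseEvent(d.time, d.amount * scale, d.duration) for d in doses]
        assert concentration(t, scaled, PARAMS) == pytest.approx(
            scale * concentration(t, doses, PARAMS), rel=1e-12
        )

    def test_monotone_washout(self):
        t = np.linspace(0.51, 24.0, 200)
        c = concentration(t, SINGLE_DOSE, PARAMS)
        assert np.all(np.diff(c) < 0)


class TestSteadyState:
    REGIMEN = Regimen(100.0, 12.0)

    def test_auc_equals_dose_over_cl(self):
        t, c = steady_state_interval(self.REGIMEN, 10.25, PARAMS, resolution=0.002)
        auc24 = np.trapezoid(c, t) * (24.0 / self.REGIMEN.interval)
        assert auc24 == pytest.approx(1025.0 / 2.20, rel=1e-3)

    def test_matches_brute_force_superposition(self):
        t, c = steady_state_interval(self.REGIMEN, 10.25, PARAMS, resolution=0.01)
        brute = steady_state_by_superposition(self.REGIMEN, 10.25, PARAMS, t)
        assert np.max(np.abs(c - brute)) < 1e-6

    def test_no_accumulation_limit(self):
        """With ke*interval huge the profile collapses to a single dose."""
        fast = IndividualParams(cl=30.0, v=3.0)  # ke = 10/h, ke*tau = 120
        t, c = steady_state_interval(self.REGIMEN, 10.25, fast, resolution=0.01)
        single = concentration(t, [DoseEvent(0.0, 512.5, 0.5)], fast)
        assert np.max(np.abs(c - single)) < 1e-9

    def test_auc_independent_of_infusion_duration(self):
        long_inf = Regimen(100.0, 12.0, infusion_duration=2.0)
        t1, c1 = steady_state_interval(self.REGIMEN, 10.25, PARAMS, resolution=0.002)
        t2, c2 = steady_state_interval(long_inf, 10.25, PARAMS, resolution=0.002)
        assert np.trapezoid(c1, t1) == pytest.approx(np.trapezoid(c2, t2), rel=1e-3)

    def test_resolution_guard(self):
        with pytest.raises(ValueError):
            steady_state_interval(self.REGIMEN, 10.25, PARAMS, resolution=0.5)


class TestRegimen:
    def test_dose_amount_per_kg(self):
        assert Regimen(100.0, 12.0).dose_amount(10.25) == pytest.approx(512.5)
        assert Regimen(75.0, 6.0).dose_amount(10.0) == pytest.approx(187.5)

    def test_interval_must_divide_day(self):
        with pytest.raises(ValueError):
            Regimen(100.0, 7.0)


class TestSerialization:
    def test_yaml_roundtrip(self, tmp_path, ref_model):
        from dataclasses import replace

        model = replace(
            ref_model,
            extra_effects=(
                CovariateEffect("egfr", "cl", "power", reference=197.0,
                                coefficient=0.1),
            ),
        )
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = PopulationModel.from_yaml(path)
        assert back == model

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PopulationModel(theta1=-1.0, theta2=3.0)
        with pytest.raises(ValueError):
            PopulationModel(theta1=2.0, theta2=3.0, omega2_cl=-0.1)
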