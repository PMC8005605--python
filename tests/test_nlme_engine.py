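"""FOCE-I estimation engine: objective, fitting, EBEs, selection."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from oracles import marginal_ofv_quadrature
from popkarc import (
    CovariateSelectionSpec,
    DoseEvent,
    Observation,
    PKDataset,
    PopulationModel,
    SamplingDesign,
    SubjectData,
    SubjectRecord,
    concentration,
    cwres,
    empirical_bayes,
    fit,
    generate_population,
    ofv_foce,
    shrinkage,
    simulate_trial,
    stepwise_select,
    typical_params,
)
from popkarc.nlme_engine import _get_param


def _shift_times(dataset, delta):
    subjects = []
    for s in dataset:
        doses = tuple(DoseEvent(d.time + delta, d.amount, d.duration) for d in s.doses)
        obs = tuple(
            Observation(o.time + delta, o.concentration, o.below_lloq)
            for o in s.observations
        )
        subjects.append(SubjectData(s.record, doses, obs))
    return PKDataset(tuple(subjects))


class TestOFV:
    def test_zero_iiv_limit_is_naive_likelihood(self, ref_model, study_dataset):
        """With Omega -> 0 the OFV reduces to -2 logL at eta = 0."""
        m = replace(ref_model, omega2_cl=0.0, omega2_v=0.0)
        expected = 0.0
        n = 0
        for subj in study_dataset:
            p = typical_params(subj.record.weight, subj.record.age, m)
            for o in subj.observations:
                r = np.log(o.concentration) - np.log(
                    concentration(o.time, list(subj.doses), p)
                )
                expected += r * r / m.sigma2
                n += 1
        expected += n * np.log(m.sigma2)
        assert ofv_foce(study_dataset, m) == pytest.approx(expected, abs=1e-6)

    def test_duplicated_subject_doubles_ofv(self, ref_model, study_dataset):
        single = PKDataset((study_dataset.subjects[0],))
        rec = study_dataset.subjects[0].record
        twin = SubjectData(
            replace(rec, subject_id="TWIN"),
            study_dataset.subjects[0].doses,
            study_dataset.subjects[0].observations,
        )
        double = PKDataset((study_dataset.subjects[0], twin))
        assert ofv_foce(double, ref_model) == pytest.approx(
            2 * ofv_foce(single, ref_model), rel=1e-10
        )

    def test_invariant_under_subject_reordering(self, ref_model, study_dataset):
        reordered = PKDataset(tuple(reversed(study_dataset.subjects)))
        assert ofv_foce(reordered, ref_model) == pytest.approx(
            ofv_foce(study_dataset, ref_model), abs=1e-5
        )

    def test_invariant_under_time_origin_shift(self, ref_model, study_dataset):
        shifted = _shift_times(study_dataset, 5.0)
        assert ofv_foce(shifted, ref_model) == pytest.approx(
            ofv_foce(study_dataset, ref_model), abs=1e-5
        )

    def test_matches_quadrature_on_small_instance(self, ref_model):
        """Single-subject OFV agrees with 64-node adaptive quadrature."""
        pop = generate_population(1, seed=21)
        ds = simulate_trial(pop, ref_model, seed=22)
        assert ofv_foce(ds, ref_model) == pytest.approx(
            marginal_ofv_quadrature(ds, ref_model), abs=0.05
        )


class TestFit:
    def test_noiseless_identifiability(self, ref_model):
        """Zero IIV and sigma -> 1e-4: thetas recovered within 0.1%."""
        truth = replace(ref_model, omega2_cl=0.0, omega2_v=0.0, sigma2=1e-8)
        pop = generate_population(20, seed=23)
        design = SamplingDesign(n_samples_probs=(0.0, 0.0, 1.0))
        ds = simulate_trial(pop, truth, design=design, seed=24)
        start = replace(truth, theta1=1.8, theta2=4.0, theta3=0.4, sigma2=1e-6)
        res = fit(ds, start, fix=("omega2_cl", "omega2_v"), compute_uncertainty=False)
        assert res.model.theta1 == pytest.approx(2.20, rel=1e-3)
        assert res.model.theta2 == pytest.approx(3.36, rel=1e-3)
        assert res.model.theta3 == pytest.approx(0.662, rel=1e-3)

    def test_study_scale_fit_outputs(self, study_fit):
        """A study-scale fit reports the full diagnostic surface."""
        assert np.isfinite(study_fit.ofv)
        assert study_fit.covariance is not None
        assert set(study_fit.rse) == set(study_fit.param_names)
        assert all(v > 0 for v in study_fit.rse.values())
        for key in ("eta_cl", "eta_v"):
            assert 0.0 <= study_fit.eta_shrinkage[key] <= 100.0
        # sparse-data eta-shrinkage lands in a plausible band
        assert 10.0 <= study_fit.eta_shrinkage["eta_cl"] <= 70.0
        assert np.isfinite(study_fit.cwres).all()

    def test_rmse_improves_with_population_size(self, ref_model):
        """RMSE of theta1 shrinks from n=20 to n=200 subjects."""
        errs = {20: [], 200: []}
        design = SamplingDesign(n_samples_probs=(0.0, 0.0, 0.0, 1.0))
        for rep in range(5):
            for n in (20, 200):
                pop = generate_population(n, seed=300 + rep)
                ds = simulate_trial(pop, ref_model, design=design, seed=400 + rep + n)
                res = fit(ds, ref_model, fast=True, compute_uncertainty=False)
                errs[n].append(res.model.theta1 - 2.20)
        rmse = {n: np.sqrt(np.mean(np.square(errs[n]))) for n in errs}
        assert rmse[200] < rmse[20]

    def test_requires_two_subjects(self, ref_model, study_dataset):
        with pytest.raises(ValueError):
            fit(PKDataset((study_dataset.subjects[0],)), ref_model)


class TestEmpiricalBayes:
    def _single_subject_dataset(self, model, eta, times, sigma=0.0):
        rec = SubjectRecord("S1", 10.25, 1.25, 0, 18.0, 76.0)
        doses = (DoseEvent(0.0, 512.5, 0.5),)
        tp = typical_params(10.25, 1.25, model)
        p = replace(tp, cl=tp.cl * np.exp(eta[0]), v=tp.v * np.exp(eta[1]))
        obs = tuple(
            Observation(t, float(concentration(t, list(doses), p))) for t in times
        )
        return PKDataset((SubjectData(rec, doses, obs),))

    def test_no_observations_gives_prior_mode(self, ref_model):
        rec = SubjectRecord("EMPTY", 10.0, 1.0, 0, 18.0, 76.0)
        ds = PKDataset((SubjectData(rec, (DoseEvent(0.0, 500.0, 0.5),), ()),))
        ebes, indiv = empirical_bayes(ds, ref_model)
        assert ebes[0] == pytest.approx([0.0, 0.0])
        tp = typical_params(10.0, 1.0, ref_model)
        assert indiv.cl[0] == pytest.approx(tp.cl)

    def test_perfect_observation_gives_zero_eta(self, ref_model):
        quiet = replace(ref_model, sigma2=1e-10)
        ds = self._single_subject_dataset(quiet, (0.0, 0.0), [2.0])
        ebes, _ = empirical_bayes(ds, quiet)
        assert np.abs(ebes).max() < 1e-6

    def test_dense_noiseless_data_recover_eta(self, ref_model):
        quiet = replace(ref_model, sigma2=1e-8)
        eta = (0.25, -0.15)
        ds = self._single_subject_dataset(
            quiet, eta, [0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
        )
        ebes, _ = empirical_bayes(ds, quiet)
        assert ebes[0] == pytest.approx(eta, abs=1e-3)


class TestShrinkage:
    def test_all_zero_ebes_full_shrinkage(self, ref_model, study_dataset):
        ebes = np.zeros((len(study_dataset), 2))
        shr = shrinkage(study_dataset, ref_model, ebes=ebes)
        assert shr["eta_cl"] == pytest.approx(100.0)
        assert shr["eta_v"] == pytest.approx(100.0)

    def test_sd_equal_to_omega_gives_zero(self, ref_model, study_dataset):
        n = len(study_dataset)
        base = np.linspace(-1.0, 1.0, n)
        base = (base - base.mean()) / base.std(ddof=1)
        ebes = np.column_stack(
            [base * np.sqrt(ref_model.omega2_cl), base * np.sqrt(ref_model.omega2_v)]
        )
        shr = shrinkage(study_dataset, ref_model, ebes=ebes)
        assert shr["eta_cl"] == pytest.approx(0.0, abs=1e-9)
        assert shr["eta_v"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_omega_reported_absent(self, ref_model, study_dataset):
        m = replace(ref_model, omega2_v=0.0)
        shr = shrinkage(study_dataset, m)
        assert shr["eta_v"] is None


class TestCWRES:
    def test_calibration_on_model_consistent_data(self, ref_model):
        """~500 observations from the model itself: mean ~0, SD ~1."""
        pop = generate_population(250, seed=31)
        design = SamplingDesign(n_samples_probs=(0.0, 1.0))
        ds = simulate_trial(pop, ref_model, design=design, seed=32)
        res = cwres(ds, ref_model)
        assert abs(np.nanmean(res)) < 0.15
        assert 0.8 <= np.nanstd(res) <= 1.2

    def test_detects_halved_clearance(self, ref_model):
        pop = generate_population(250, seed=31)
        design = SamplingDesign(n_samples_probs=(0.0, 1.0))
        ds = simulate_trial(pop, ref_model, design=design, seed=32)
        wrong = replace(ref_model, theta1=ref_model.theta1 / 2)
        res = cwres(ds, wrong)
        assert abs(np.nanmean(res)) > 0.5

    def test_study_scale_residuals_mostly_within_two(self, study_fit):
        inside = np.mean(np.abs(study_fit.cwres) <= 2.0)
        assert inside >= 0.9


class TestStepwiseSelection:
    @pytest.fixture(scope="class")
    def selection_run(self, ref_model):
        pop = generate_population(40, seed=33)
        ds = simulate_trial(pop, ref_model, seed=34)
        base = replace(ref_model, theta3=None)
        spec = CovariateSelectionSpec(
            base_model=base,
            candidates=(("age", "cl", "power"), ("sex", "cl", "proportional")),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, trace = stepwise_select(ds, spec, refit_final=False)
        return ds, base, spec, final, trace

    def test_age_effect_found_and_strict_boundary(self, selection_run):
        ds, base, spec, final, trace = selection_run
        added = trace[trace.decision == "added"]
        assert "age_cl" in set(added.candidate)
        delta = float(
            trace[(trace.candidate == "age_cl") & (trace.decision == "added")]
            .delta_ofv.iloc[0]
        )
        assert delta > spec.forward_threshold
        # a threshold exactly equal to the observed drop must block addition
        strict = replace(
            spec, forward_threshold=delta, backward_threshold=delta + 1.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final2, trace2 = stepwise_select(ds, strict, refit_final=False)
        assert "age_cl" not in {
            e.label for e in final2.model.extra_effects
        } and final2.model.theta3 is None

    def test_accepted_steps_strictly_decrease_ofv(self, selection_run):
        _, _, spec, final, trace = selection_run
        added = trace[trace.decision == "added"]
        assert (added.delta_ofv > spec.forward_threshold).all()
        first = trace[trace.decision == "tested"].iloc[0]
        base_ofv = float(first.ofv + first.delta_ofv)
        n_kept = len(added) - len(trace[trace.decision == "removed"])
        assert final.ofv <= base_ofv - spec.forward_threshold * max(n_kept, 0)

    def test_selected_age_effect_folds_into_theta3(self, selection_run):
        *_, final, _ = selection_run
        assert final.model.theta3 is not None
        assert 0.2 < final.model.theta3 < 1.4
        assert not any(
            e.covariate == "age" and e.parameter == "cl"
            for e in final.model.extra_effects
        )

    def test_threshold_validation(self, ref_model):
        with pytest.raises(ValueError):
            CovariateSelectionSpec(
                base_model=ref_model, forward_threshold=7.0, backward_threshold=3.84
            )
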