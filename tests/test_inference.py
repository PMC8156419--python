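"""Error models, likelihoods, individual/pooled fits, residual diagnostics."""

import math

import numpy as np
import pytest

from serinepk.datatypes import DoseEvent, FullParams, StructuralParams, make_subject
from serinepk.inference import (
    ErrorParams,
    FitResult,
    fit_individual,
    fit_naive_pooled,
    naive_pooled_condition_numbers,
    pooled_nll_full,
    residual_normality_report,
    residual_sd,
    subject_nll,
)
from serinepk.model import simulate_concentration
from serinepk.synthetic import TrialDesign, default_generating_model, generate_trial


class TestResidualSd:
    @pytest.mark.parametrize(
        "err, predicted, expected",
        [
            (ErrorParams(sigma_add=5.0, model_kind="constant"), 300.0, 5.0),
            (ErrorParams(sigma_prop=0.1, model_kind="proportional"), 200.0, 20.0),
            (ErrorParams(5.0, 0.1, "combined"), 0.0, 5.0),
            (ErrorParams(5.0, 0.1, "combined"), 120.0, 13.0),  # sqrt(25 + 144)
        ],
    )
    def test_values(self, err, predicted, expected):
        assert residual_sd(predicted, err) == pytest.approx(expected)

    def test_negative_prediction_rejected(self):
        with pytest.raises(ValueError):
            residual_sd(-1.0, ErrorParams(sigma_add=5.0, model_kind="constant"))

    def test_kind_consistency_enforced(self):
        with pytest.raises(ValueError):
            ErrorParams(sigma_add=1.0, sigma_prop=0.1, model_kind="constant")
        with pytest.raises(ValueError):
            ErrorParams(sigma_add=1.0, sigma_prop=0.1, model_kind="proportional")
        with pytest.raises(ValueError):
            ErrorParams(sigma_add=-1.0, model_kind="constant")


class TestSubjectNll:
    def _toy(self, pop_params):
        times = [0.5, 2.0, 6.0]
        conc = simulate_concentration(pop_params, [DoseEvent(0.0, 1e5)], times)
        y = conc + np.array([3.0, -5.0, 2.0])
        return make_subject("T", [0.0], [1e5], times, y)

    def test_matches_literal_loop(self, pop_params):
        """Agreement with an explicit per-observation loop on a 3-point toy."""
        subj = self._toy(pop_params)
        err = ErrorParams(5.0, 0.1, "combined")
        expected = 0.0
        for obs in subj.observations:
            f = float(simulate_concentration(pop_params, subj.doses, [obs.time])[0])
            s = math.sqrt(5.0**2 + (0.1 * f) ** 2)
            expected += math.log(s) + 0.5 * ((obs.concentration - f) / s) ** 2
            expected += 0.5 * math.log(2 * math.pi)
        assert subject_nll(subj, pop_params, err) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_observation_order(self, pop_params):
        subj = self._toy(pop_params)
        shuffled = make_subject(
            "T",
            [0.0],
            [1e5],
            [o.time for o in reversed(subj.observations)],
            [o.concentration for o in reversed(subj.observations)],
        )
        err = ErrorParams(5.0, 0.1, "combined")
        assert subject_nll(subj, pop_params, err) == pytest.approx(
            subject_nll(shuffled, pop_params, err), rel=1e-12
        )

    def test_additive_over_observations(self, pop_params):
        subj = self._toy(pop_params)
        err = ErrorParams(5.0, 0.1, "combined")
        parts = [
            subject_nll(
                make_subject("p", [0.0], [1e5], [o.time], [o.concentration]), pop_params, err
            )
            for o in subj.observations
        ]
        assert subject_nll(subj, pop_params, err) == pytest.approx(sum(parts), rel=1e-12)

    def test_doubling_sigma_on_exact_data(self, pop_params):
        """With zero residuals the NLL rises by exactly n·log 2."""
        times = [0.5, 2.0, 6.0]
        conc = simulate_concentration(pop_params, [DoseEvent(0.0, 1e5)], times)
        subj = make_subject("T", [0.0], [1e5], times, conc)
        n1 = subject_nll(subj, pop_params, ErrorParams(sigma_add=4.0, model_kind="constant"))
        n2 = subject_nll(subj, pop_params, ErrorParams(sigma_add=8.0, model_kind="constant"))
        assert n2 - n1 == pytest.approx(3 * math.log(2), rel=1e-12)

    def test_zero_sigma_rejected(self, pop_params):
        subj = self._toy(pop_params)
        with pytest.raises(ValueError):
            subject_nll(subj, pop_params, ErrorParams(model_kind="combined"))


class TestFitIndividual:
    def test_noiseless_recovery(self, noiseless_subject, pop_params):
        fit = fit_individual(
            noiseless_subject,
            StructuralParams(2.0, 0.005, 0.3, 30.0),
            err_kind="combined",
            multistart=4,
            seed=0,
        )
        assert fit.converged
        for name, truth in [
            ("k_abs", 2.88),
            ("f_over_v", 0.00429),
            ("cl_over_v", 0.288),
            ("kgen_over_v", 29.6),
        ]:
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-4)

    def test_recovery_from_distant_start(self, noiseless_subject):
        """Any start within 10x of truth recovers the generating values."""
        fit = fit_individual(
            noiseless_subject,
            StructuralParams(2.88 / 8, 0.00429 * 8, 0.288 * 5, 29.6 / 5),
            err_kind="combined",
            multistart=6,
            seed=1,
        )
        assert fit.estimates["cl_over_v"] == pytest.approx(0.288, rel=1e-4)
        assert fit.estimates["k_abs"] == pytest.approx(2.88, rel=1e-4)

    def test_observation_order_does_not_change_optimum(self, noiseless_subject):
        perm = make_subject(
            "S01p",
            [d.time for d in noiseless_subject.doses],
            [d.amount for d in noiseless_subject.doses],
            [o.time for o in reversed(noiseless_subject.observations)],
            [o.concentration for o in reversed(noiseless_subject.observations)],
        )
        init = StructuralParams(2.0, 0.005, 0.3, 30.0)
        f1 = fit_individual(noiseless_subject, init, multistart=2, seed=0)
        f2 = fit_individual(perm, init, multistart=2, seed=0)
        for n in ("k_abs", "f_over_v", "cl_over_v", "kgen_over_v"):
            assert f1.estimates[n] == pytest.approx(f2.estimates[n], rel=1e-6)

    def test_too_few_observations_rejected(self, pop_params):
        subj = make_subject("S", [0.0], [1e5], [1.0, 2.0, 3.0], [100.0, 120.0, 110.0])
        with pytest.raises(ValueError):
            fit_individual(subj, pop_params)

    def test_dispersion_pattern_across_subjects(self):
        """Absorption spreads far more than elimination across fitted subjects.

        The generator puts fourfold more log-scale variability on k_abs than
        on CL/V; per-subject fits must reproduce that dispersion ordering.
        """
        subs = generate_trial(TrialDesign(), default_generating_model(11))
        init = StructuralParams(2.0, 0.005, 0.3, 30.0)
        ka, cl = [], []
        for s in subs:
            fit = fit_individual(s, init, err_kind="proportional", multistart=2, seed=0)
            ka.append(fit.estimates["k_abs"])
            cl.append(fit.estimates["cl_over_v"])
        cv_ka = np.std(np.log(ka))
        cv_cl = np.std(np.log(cl))
        assert cv_ka > 2.0 * cv_cl

    def test_dose_unit_invariance(self, pop_params, noiseless_subject):
        """Rescaling dose amounts rescales only F/V, inversely."""
        scale = 105.09e-6  # i.e. recording doses in grams instead of µmol
        scaled = make_subject(
            "S01s",
            [d.time for d in noiseless_subject.doses],
            [d.amount * scale for d in noiseless_subject.doses],
            [o.time for o in noiseless_subject.observations],
            [o.concentration for o in noiseless_subject.observations],
        )
        init = StructuralParams(2.0, 0.005, 0.3, 30.0)
        f1 = fit_individual(noiseless_subject, init, multistart=2, seed=0)
        f2 = fit_individual(
            scaled, StructuralParams(2.0, 0.005 / scale, 0.3, 30.0), multistart=2, seed=0
        )
        assert f2.estimates["f_over_v"] == pytest.approx(f1.estimates["f_over_v"] / scale, rel=1e-3)
        for n in ("k_abs", "cl_over_v", "kgen_over_v"):
            assert f2.estimates[n] == pytest.approx(f1.estimates[n], rel=1e-3)


@pytest.fixture(scope="module")
def pooled_fit():
    # zero IIV isolates structural (ratio) identifiability from the
    # averaging distortion that pooling inflicts on heterogeneous subjects
    gen = default_generating_model(3)
    pop = gen.population
    from serinepk.population import PopulationModel

    no_iiv = PopulationModel(
        pop.theta, {n: 0.0 for n in pop.omega2}, {n: True for n in pop.omega_fixed}, pop.err
    )
    subs = generate_trial(TrialDesign(), type(gen)(no_iiv, gen.seed))
    fit = fit_naive_pooled(
        subs, FullParams(1.0, 0.5, 2.0, 30.0, 0.3), err_kind="proportional", multistart=2
    )
    return subs, fit


class TestNaivePooled:
    def test_scaling_ridge(self, pooled_fit):
        """Scaling {V, F, k_gen, CL} together leaves the objective unchanged."""
        subs, fit = pooled_fit
        est = fit.estimates
        err = ErrorParams(sigma_prop=est["sigma_prop"], model_kind="proportional")
        p1 = FullParams(est["v_d"], est["f"], est["k_abs"], est["k_gen"], est["cl"])
        p2 = FullParams(
            est["v_d"] * 10, est["f"] * 10, est["k_abs"], est["k_gen"] * 10, est["cl"] * 10
        )
        a = pooled_nll_full(subs, p1, err)
        b = pooled_nll_full(subs, p2, err)
        assert abs(b - a) / abs(a) < 1e-8

    def test_ratios_identifiable_despite_ridge(self, pooled_fit):
        subs, fit = pooled_fit
        est = fit.estimates
        assert est["f"] / est["v_d"] == pytest.approx(0.00429, rel=0.05)
        assert est["cl"] / est["v_d"] == pytest.approx(0.288, rel=0.05)
        assert est["k_gen"] / est["v_d"] == pytest.approx(29.6, rel=0.05)

    def test_conditioning_gap(self, pooled_fit):
        """The 5-parameter Hessian is at least 100x worse conditioned."""
        subs, fit = pooled_fit
        cond_full, cond_ratio = naive_pooled_condition_numbers(subs, fit, err_kind="proportional")
        assert cond_full >= 100.0 * cond_ratio

    def test_requires_two_subjects(self, noiseless_subject):
        with pytest.raises(ValueError):
            fit_naive_pooled([noiseless_subject], FullParams(1.0, 0.5, 2.0, 30.0, 0.3))


class TestResidualNormality:
    @staticmethod
    def _fit_with_residuals(residuals):
        return FitResult(
            estimates={},
            objective=0.0,
            residuals=np.asarray(residuals, dtype=float),
            converged=True,
            n_function_evals=0,
        )

    def test_standard_normal_slope(self):
        rng = np.random.default_rng(0)
        rep = residual_normality_report(self._fit_with_residuals(rng.normal(size=80)))
        assert 0.9 <= rep.qq_slope <= 1.1
        assert not rep.degenerate

    def test_constant_residuals_degenerate(self):
        rep = residual_normality_report(self._fit_with_residuals(np.ones(10)))
        assert rep.degenerate

    def test_heavy_tails_detected(self):
        rng = np.random.default_rng(1)
        normal = residual_normality_report(self._fit_with_residuals(rng.normal(size=200)))
        heavy = residual_normality_report(self._fit_with_residuals(rng.standard_t(2, size=200)))
        assert heavy.tail_deviation > normal.tail_deviation

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            residual_normality_report(self._fit_with_residuals([0.1, -0.2]))

    @pytest.mark.parametrize("seed", [2, 5, 7])
    def test_matched_error_model_gives_straighter_tails(self, pop_params, seed):
        """Fitting combined-error data with a combined model straightens the
        QQ tails relative to a constant-error fit of the same data.

        One densely sampled subject (n = 80) so the residual pool is large
        relative to the parameter count.
        """
        rng = np.random.default_rng(seed)
        times = np.linspace(0.25, 24.0, 80)
        doses = [DoseEvent(0.0, 190_313.0)]
        err = ErrorParams(3.0, 0.15, "combined")
        clean = simulate_concentration(pop_params, doses, times)
        sd = residual_sd(clean, err)
        y = np.clip(clean + rng.normal(size=times.size) * sd, 0.5, None)
        subj = make_subject("S", [0.0], [190_313.0], times, y)
        init = StructuralParams(2.0, 0.005, 0.3, 30.0)
        fc = fit_individual(subj, init, err_kind="combined", multistart=2, seed=0)
        fk = fit_individual(subj, init, err_kind="constant", multistart=2, seed=0)
        assert residual_normality_report(fc).tail_deviation < residual_normality_report(fk).tail_deviation
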