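"""Mixed-effects estimation: Laplace objective, LRT, covariate screening."""

import math

import numpy as np
import pytest

from serinepk.inference import ErrorParams, subject_nll
from serinepk.datatypes import StructuralParams
from serinepk.population import (
    PopulationFit,
    PopulationModel,
    compare_nested,
    covariate_screen,
    fit_population,
    lrt_threshold,
    marginal_nll_gauss_hermite,
    marginal_nll_laplace,
)
from serinepk.synthetic import TrialDesign, default_fit_init, default_generating_model, generate_trial


def _reduced_model(omega2):
    return PopulationModel.from_values(
        2.88, 0.00429, 0.288, 29.6,
        omega2=omega2,
        err=ErrorParams(sigma_prop=0.1, model_kind="proportional"),
    )


@pytest.fixture(scope="module")
def small_trial():
    return generate_trial(TrialDesign(n_subjects=3), default_generating_model(7))


@pytest.fixture(scope="module")
def trial_10():
    return generate_trial(TrialDesign(), default_generating_model(1))


class TestLaplaceObjective:
    def test_matches_gauss_hermite_one_eta(self, small_trial):
        """Laplace vs 64-node adaptive Gauss-Hermite on a 1-eta model."""
        m = _reduced_model({"k_abs": 0.16})
        lap = marginal_nll_laplace(m, small_trial)
        gh = marginal_nll_gauss_hermite(m, small_trial, n_nodes=64)
        assert abs(lap - gh) / abs(gh) < 1e-3

    def test_matches_gauss_hermite_two_etas(self, small_trial):
        m = _reduced_model({"k_abs": 0.16, "cl_over_v": 0.01})
        lap = marginal_nll_laplace(m, small_trial)
        gh = marginal_nll_gauss_hermite(m, small_trial, n_nodes=64)
        assert abs(lap - gh) / abs(gh) < 1e-3

    def test_vanishing_variance_reaches_fixed_effect_limit(self, small_trial):
        """As every omega² shrinks, the objective approaches the plain NLL."""
        typical = StructuralParams(2.88, 0.00429, 0.288, 29.6)
        err = ErrorParams(sigma_prop=0.1, model_kind="proportional")
        fixed_obj = 2.0 * sum(subject_nll(s, typical, err) for s in small_trial)
        m = _reduced_model({"k_abs": 1e-8, "cl_over_v": 1e-8})
        assert marginal_nll_laplace(m, small_trial) == pytest.approx(fixed_obj, rel=1e-6)

    def test_zero_variance_is_exactly_the_fixed_effect_objective(self, small_trial):
        typical = StructuralParams(2.88, 0.00429, 0.288, 29.6)
        err = ErrorParams(sigma_prop=0.1, model_kind="proportional")
        fixed_obj = 2.0 * sum(subject_nll(s, typical, err) for s in small_trial)
        m = _reduced_model({})
        assert marginal_nll_laplace(m, small_trial) == pytest.approx(fixed_obj, rel=1e-12)

    def test_invariant_to_subject_order(self, small_trial):
        m = _reduced_model({"k_abs": 0.16})
        assert marginal_nll_laplace(m, small_trial) == pytest.approx(
            marginal_nll_laplace(m, list(reversed(small_trial))), rel=1e-10
        )


@pytest.fixture(scope="module")
def fit(trial_10):
    return fit_population(trial_10, default_fit_init("proportional"), seed=1)


class TestFitPopulation:
    def test_estimates_near_generating_values(self, fit):
        assert fit.estimates["cl_over_v"] == pytest.approx(0.288, rel=0.10)
        assert fit.estimates["kgen_over_v"] == pytest.approx(29.6, rel=0.10)

    def test_zero_iiv_variances_collapse(self, fit):
        """Parameters simulated without variability get their omega fixed."""
        assert "f_over_v" in fit.collapsed
        assert fit.model.omega2["f_over_v"] == 0.0
        assert fit.model.omega_fixed["f_over_v"]

    def test_refit_from_optimum_is_idempotent(self, trial_10, fit):
        refit = fit_population(trial_10, fit.model, seed=1, refit_collapsed=False)
        assert refit.objective == pytest.approx(fit.objective, abs=0.01)

    def test_ebe_count_matches_subjects(self, fit, trial_10):
        assert len(fit.ebe) == len(trial_10)

    def test_freeing_a_variance_never_worsens_the_objective(self, trial_10):
        """Nested structures: the bigger model attains at most the smaller's
        optimum (up to optimizer slack)."""
        init_small = _reduced_model({"k_abs": 0.16})
        small = fit_population(trial_10, init_small, seed=3, refit_collapsed=False)
        big_init = PopulationModel(
            small.model.theta,
            {**small.model.omega2, "cl_over_v": 0.02},
            {**small.model.omega_fixed, "cl_over_v": False},
            small.model.err,
        )
        big = fit_population(trial_10, big_init, seed=3, refit_collapsed=False)
        assert big.objective <= small.objective + 0.05

    def test_needs_two_subjects(self, trial_10):
        with pytest.raises(ValueError):
            fit_population(trial_10[:1], default_fit_init("proportional"))

    def test_se_ranges_bracket_estimates(self, trial_10):
        fit = fit_population(
            trial_10, default_fit_init("proportional"), seed=1, compute_se=True
        )
        ranges = fit.theta_se_ranges()
        assert ranges is not None
        for n, (lo, hi) in ranges.items():
            assert lo < fit.estimates[n] < hi


class TestLrt:
    @pytest.mark.parametrize(
        "extra, alpha, expected, tol",
        [(2, 0.05, 5.99, 0.01), (1, 0.05, 3.84, 0.01), (1, 0.999, 0.0, 2e-6)],
    )
    def test_threshold(self, extra, alpha, expected, tol):
        assert lrt_threshold(extra, alpha) == pytest.approx(expected, abs=tol)

    def test_threshold_rejects_bad_input(self):
        with pytest.raises(ValueError):
            lrt_threshold(0, 0.05)
        with pytest.raises(ValueError):
            lrt_threshold(1, 1.5)

    def test_identical_fits_not_significant(self, trial_10):
        fit = fit_population(trial_10, default_fit_init("proportional"), seed=1)
        cmp = compare_nested(fit, fit, extra_params=2)
        assert cmp.delta_objective == 0.0
        assert not cmp.significant
        assert cmp.max_prediction_change == 0.0

    def test_worse_big_model_warns(self, trial_10):
        fit = fit_population(trial_10, default_fit_init("proportional"), seed=1)
        worse = PopulationFit(
            model=fit.model, objective=fit.objective + 5.0, converged=True, ebe=fit.ebe
        )
        cmp = compare_nested(fit, worse, extra_params=2)
        assert cmp.warning is not None

    def test_two_compartment_fit_on_one_compartment_data(self, trial_10):
        """Adding an inert peripheral compartment buys no real improvement."""
        init = PopulationModel.from_values(
            2.0, 0.005, 0.3, 30.0,
            omega2={"k_abs": 0.04, "cl_over_v": 0.04},
            err=ErrorParams(sigma_prop=0.1, model_kind="proportional"),
        )
        small = fit_population(trial_10, init, seed=1, refit_collapsed=False)
        theta2 = dict(small.model.theta)
        theta2["k23"] = math.log(0.01)
        theta2["k32"] = math.log(0.01)
        big_init = PopulationModel(
            theta2, small.model.omega2, small.model.omega_fixed, small.model.err
        )
        big = fit_population(trial_10, big_init, seed=1, refit_collapsed=False)
        cmp = compare_nested(small, big, extra_params=2)
        assert cmp.delta_objective < cmp.threshold
        assert cmp.max_prediction_change < 0.05


class TestCovariateScreen:
    @staticmethod
    def _fit_with_etas(etas):
        model = PopulationModel.from_values(2.88, 0.00429, 0.288, 29.6, omega2={"k_abs": 0.16})
        return PopulationFit(model=model, objective=0.0, converged=True, ebe=etas)

    def test_requires_three_subjects(self, trial_10):
        fit = self._fit_with_etas([{"k_abs": 0.1}, {"k_abs": -0.1}])
        with pytest.raises(ValueError):
            covariate_screen(fit, trial_10[:2])

    def test_independent_etas_mostly_pass(self, trial_10):
        """Etas unrelated to the covariates: 'no covariate' verdict in the
        bulk of replicates (each screen runs four tests, so occasional
        chance hits are expected)."""
        rng = np.random.default_rng(5)
        verdicts = []
        for _ in range(10):
            etas = [{"k_abs": float(e)} for e in rng.normal(0, 0.4, size=len(trial_10))]
            screen = covariate_screen(
                self._fit_with_etas(etas), trial_10, n_permutations=500, seed=0
            )
            verdicts.append(screen.verdict == "no covariate")
        assert sum(verdicts) >= 7

    def test_strongly_correlated_eta_detected(self, trial_10):
        rng = np.random.default_rng(6)
        w = np.array([s.weight for s in trial_10])
        z = (w - w.mean()) / w.std()
        etas = [{"k_abs": float(0.99 * zi + 0.01 * ri)} for zi, ri in zip(z, rng.normal(size=z.size))]
        screen = covariate_screen(self._fit_with_etas(etas), trial_10, n_permutations=2000, seed=0)
        weight_rec = [r for r in screen.records if r["covariate"] == "weight"][0]
        assert weight_rec["pearson_p"] < 0.01
        assert screen.verdict == "covariate signal detected"

    def test_constant_covariate_skipped(self, trial_10):
        subs = [
            type(s)(s.subject_id, s.doses, s.observations, weight=70.0, height=s.height)
            for s in trial_10
        ]
        etas = [{"k_abs": 0.1 * i} for i in range(len(subs))]
        screen = covariate_screen(self._fit_with_etas(etas), subs, n_permutations=500, seed=0)
        assert any("weight" in s for s in screen.skipped)

    def test_affine_covariate_recoding_invariance(self, trial_10):
        rng = np.random.default_rng(8)
        etas = [{"k_abs": float(e)} for e in rng.normal(0, 0.4, size=len(trial_10))]
        fit = self._fit_with_etas(etas)
        s1 = covariate_screen(fit, trial_10, n_permutations=1000, seed=3)
        rescaled = [
            type(s)(s.subject_id, s.doses, s.observations,
                    weight=2.2 * s.weight + 1.0, height=s.height / 100.0)
            for s in trial_10
        ]
        s2 = covariate_screen(fit, rescaled, n_permutations=1000, seed=3)
        for r1, r2 in zip(s1.records, s2.records):
            assert r1["pearson_r"] == pytest.approx(r2["pearson_r"], abs=1e-12)
            assert r1["pearson_p"] == pytest.approx(r2["pearson_p"], abs=1e-12)
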