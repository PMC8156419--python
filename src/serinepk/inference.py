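"""Residual error models, per-subject and naive pooled fits, diagnostics.

Individual subjects are fitted by maximum likelihood under a Gaussian
residual model whose standard deviation may be constant, proportional to the
prediction, or combined (variance-additive:  sqrt(a² + (b·f)²), the standard
pharmacometric convention).  Optimization runs in log-parameter space with
multistart to guard against local minima.

The naive pooled fit deliberately uses the non-ratio five-parameter form
(V_D, F, k_abs, k_gen, CL): oral concentration data cannot separate a common
scaling of {V_D, F, k_gen, CL}, so the pooled objective has an exact flat
ridge.  The package keeps this fit as a structural-identifiability
demonstration of why the ratio parameterization is the one to estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import _numdiff
from .datatypes import FullParams, StructuralParams, SubjectData
from .model import simulate_concentration

__all__ = [
    "ErrorParams",
    "FitResult",
    "residual_sd",
    "subject_nll",
    "fit_individual",
    "fit_naive_pooled",
    "pooled_nll_full",
    "pooled_nll_ratio",
    "naive_pooled_condition_numbers",
    "residual_normality_report",
]

_LOG_2PI = math.log(2.0 * math.pi)

STRUCTURAL_NAMES = ("k_abs", "f_over_v", "cl_over_v", "kgen_over_v")
FULL_NAMES = ("v_d", "f", "k_abs", "k_gen", "cl")


@dataclass(frozen=True)
class ErrorParams:
    """Residual error model: constant, proportional, or combined.

    All-zero sigmas describe a degenerate noiseless model: valid for
    simulation, but any likelihood evaluation will raise on the zero
    residual SD.
    """

    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    model_kind: str = "combined"

    def __post_init__(self) -> None:
        if self.model_kind not in ("constant", "proportional", "combined"):
            raise ValueError(f"unknown error model {self.model_kind!r}")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("error sigmas must be non-negative")
        if self.model_kind == "constant" and self.sigma_prop != 0:
            raise ValueError("constant error model requires sigma_prop = 0")
        if self.model_kind == "proportional" and self.sigma_add != 0:
            raise ValueError("proportional error model requires sigma_add = 0")


def residual_sd(predicted, err: ErrorParams):
    """Residual standard deviation at the given prediction(s), µmol/L."""
    pred = np.asarray(predicted, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be non-negative")
    if err.model_kind == "constant":
        sd = np.full_like(pred, err.sigma_add)
    elif err.model_kind == "proportional":
        sd = err.sigma_prop * pred
    else:
        sd = np.sqrt(err.sigma_add**2 + (err.sigma_prop * pred) ** 2)
    return float(sd) if np.isscalar(predicted) else sd


def subject_nll(subject: SubjectData, params: StructuralParams, err: ErrorParams) -> float:
    """Gaussian negative log-likelihood of one subject's observations.

    Σ_j [ log σ_j + ((y_j - f_j)/σ_j)²/2 + log(2π)/2 ] with predictions f
    from the structural model and σ from the residual error model.  Additive
    over observations and invariant to their ordering.
    """
    t = np.asarray(subject.obs_times, dtype=float)
    y = np.asarray(subject.obs_concentrations, dtype=float)
    order = np.argsort(t, kind="stable")
    pred = np.empty_like(t)
    pred[order] = simulate_concentration(params, subject.doses, t[order])
    sd = residual_sd(pred, err)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("residual SD is zero at one or more observations")
    z = (y - pred) / sd
    return float(np.sum(np.log(sd) + 0.5 * z**2 + 0.5 * _LOG_2PI))


@dataclass
class FitResult:
    """Outcome of a likelihood fit.

    ``objective`` is on the -2·log-likelihood scale; ``residuals`` are the
    weighted residuals (y - f)/σ in observation order.
    """

    estimates: dict[str, float]
    objective: float
    residuals: np.ndarray
    converged: bool
    n_function_evals: int
    standard_errors: dict[str, float] | None = None
    message: str = ""


def _error_param_layout(err_kind: str) -> list[str]:
    return {
        "constant": ["sigma_add"],
        "proportional": ["sigma_prop"],
        "combined": ["sigma_add", "sigma_prop"],
    }[err_kind]


def _build_error(err_kind: str, values: dict[str, float]) -> ErrorParams:
    return ErrorParams(
        sigma_add=values.get("sigma_add", 0.0),
        sigma_prop=values.get("sigma_prop", 0.0),
        model_kind=err_kind,
    )


def _weighted_residuals(subject: SubjectData, params: StructuralParams, err: ErrorParams) -> np.ndarray:
    t = np.asarray(subject.obs_times, dtype=float)
    y = np.asarray(subject.obs_concentrations, dtype=float)
    order = np.argsort(t, kind="stable")
    pred = np.empty_like(t)
    pred[order] = simulate_concentration(params, subject.doses, t[order])
    return (y - pred) / residual_sd(pred, err)


_LOG_PARAM_CLIP = 30.0


def _safe_objective_value(fn, x: np.ndarray) -> float:
    """Evaluate a log-parameter NLL keeping the optimizer's world finite.

    Wild line-search points are clipped back into a huge-but-finite box with
    a quadratic penalty, and any non-finite likelihood becomes a large
    constant instead of inf/NaN (which would abort L-BFGS-B line searches).
    """
    xc = np.clip(x, -_LOG_PARAM_CLIP, _LOG_PARAM_CLIP)
    penalty = 1e3 * float(np.sum((x - xc) ** 2))
    try:
        with np.errstate(all="ignore"):
            val = fn(np.exp(xc))
    except (ValueError, OverflowError, FloatingPointError):
        return 1e12
    if not np.isfinite(val):
        return 1e12
    return val + penalty


def _multistart_minimize(objective, x0, multistart, seed, bounds=None):
    """L-BFGS-B from x0 and (multistart-1) log-uniform ±1 perturbations."""
    rng = np.random.default_rng(seed)
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(max(multistart - 1, 0)):
        starts.append(starts[0] + rng.uniform(-1.0, 1.0, size=len(x0)))
    best = None
    n_evals = 0
    any_success = False
    opts = {"ftol": 1e-14, "gtol": 1e-10, "maxfun": 20000}
    for s in starts:
        try:
            res = optimize.minimize(objective, s, method="L-BFGS-B", bounds=bounds, options=opts)
        except (ValueError, FloatingPointError):
            continue
        n_evals += res.nfev
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, n_evals, any_success


def _profiled_error(pred: np.ndarray, y: np.ndarray, err_kind: str, r: float = 0.0) -> ErrorParams:
    """Error parameters maximizing the likelihood at fixed predictions.

    For a Gaussian likelihood the overall error scale has a closed-form
    maximizer (extended least squares): constant -> σ̂² = SSE/n,
    proportional -> σ̂² = mean((y-f)²/f²), combined with shape ratio
    r = σ_prop/σ_add -> σ̂_add² = mean((y-f)²/(1+(r f)²)).  Profiling the
    scale removes the badly scaled joint descent direction between sigmas
    and structural parameters.
    """
    resid = y - pred
    if err_kind == "constant":
        a2 = float(np.mean(resid**2))
        return ErrorParams(sigma_add=math.sqrt(max(a2, 1e-290)), model_kind="constant")
    if err_kind == "proportional":
        s2 = float(np.mean((resid / pred) ** 2))
        return ErrorParams(sigma_prop=math.sqrt(max(s2, 1e-290)), model_kind="proportional")
    w = 1.0 + (r * pred) ** 2
    a2 = float(np.mean(resid**2 / w))
    a = math.sqrt(max(a2, 1e-290))
    return ErrorParams(sigma_add=a, sigma_prop=r * a, model_kind="combined")


def _concentrated_nll(pred: np.ndarray, y: np.ndarray, err: ErrorParams) -> float:
    var = np.maximum(np.asarray(residual_sd(pred, err), dtype=float) ** 2, 1e-290)
    n = y.size
    return float(0.5 * np.sum(np.log(var)) + 0.5 * n * (1.0 + _LOG_2PI))


def _canonical_flip(v: np.ndarray) -> np.ndarray:
    """Resolve absorption/elimination flip-flop by convention.

    The one-compartment oral curve is invariant under swapping k_abs and
    CL/V while rescaling F/V and k_gen/V by their ratio, so both modes are
    exact global optima.  Estimates are reported on the branch with
    absorption at least as fast as elimination (k_abs ≥ CL/V), the
    physiological reading for serine.  ``v`` is (k_abs, F/V, CL/V, k_gen/V).
    """
    ka, fv, ke, kg = v[:4]
    if ka >= ke:
        return v
    out = v.copy()
    out[0], out[2] = ke, ka
    out[1] = fv * ka / ke
    out[3] = kg * ka / ke
    return out


def _sorted_obs(subject: SubjectData) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(subject.obs_times, dtype=float)
    order = np.argsort(t, kind="stable")
    return t[order], np.asarray(subject.obs_concentrations, dtype=float)[order]


def fit_individual(
    subject: SubjectData,
    init: StructuralParams,
    err_kind: str = "combined",
    bounds: Sequence[tuple[float, float]] | None = None,
    multistart: int = 8,
    seed: int = 0,
    compute_se: bool = False,
) -> FitResult:
    """Maximum-likelihood fit of one subject's ratio parameters.

    Optimizes log(k_abs, F/V, CL/V, k_gen/V) — plus, for the combined error
    model, the log shape ratio σ_prop/σ_add — by multistart L-BFGS-B, with
    the overall error scale profiled out in closed form.  Estimates are
    returned in natural units.
    """
    if len(subject.observations) < 4:
        raise ValueError("need at least 4 observations to fit 4 structural parameters")
    t, y = _sorted_obs(subject)
    names = list(STRUCTURAL_NAMES) + (["_shape_r"] if err_kind == "combined" else [])
    x0 = np.log([getattr(init, n) for n in STRUCTURAL_NAMES] + ([0.02] if err_kind == "combined" else []))

    def objective(x):
        def nll(v):
            p = StructuralParams(*v[:4])
            r = v[4] if err_kind == "combined" else 0.0
            pred = simulate_concentration(p, subject.doses, t)
            err = _profiled_error(pred, y, err_kind, r)
            return _concentrated_nll(pred, y, err)

        return _safe_objective_value(nll, x)

    best, n_evals, ok = _multistart_minimize(objective, x0, multistart, seed, bounds)
    if best is None:
        return FitResult(
            estimates={n: math.nan for n in list(STRUCTURAL_NAMES) + _error_param_layout(err_kind)},
            objective=math.nan,
            residuals=np.full(len(subject.observations), np.nan),
            converged=False,
            n_function_evals=n_evals,
            message="all starts failed",
        )
    v = np.exp(best.x)
    v[:4] = _canonical_flip(v[:4])
    p = StructuralParams(*v[:4])
    pred = simulate_concentration(p, subject.doses, t)
    e = _profiled_error(pred, y, err_kind, v[4] if err_kind == "combined" else 0.0)
    est = {n: float(val) for n, val in zip(STRUCTURAL_NAMES, v)}
    est["sigma_add"] = e.sigma_add
    est["sigma_prop"] = e.sigma_prop
    se = None
    if compute_se:
        hess = _numdiff.hessian(objective, best.x)
        se = _log_scale_se(hess, names)
    return FitResult(
        estimates=est,
        objective=2.0 * best.fun,
        residuals=_weighted_residuals(subject, p, e),
        converged=ok,
        n_function_evals=n_evals,
        standard_errors=se,
        message=str(best.message),
    )


def _log_scale_se(hess: np.ndarray, names: list[str]) -> dict[str, float] | None:
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag < 0):
        return None
    return dict(zip(names, np.sqrt(diag)))


def pooled_nll_full(subjects: Sequence[SubjectData], params: FullParams, err: ErrorParams) -> float:
    """Pooled NLL of the five-parameter form (all subjects, one parameter set)."""
    ratios = params.to_ratios()
    return sum(subject_nll(s, ratios, err) for s in subjects)


def pooled_nll_ratio(subjects: Sequence[SubjectData], params: StructuralParams, err: ErrorParams) -> float:
    """Pooled NLL of the ratio form (all subjects, one parameter set)."""
    return sum(subject_nll(s, params, err) for s in subjects)


def fit_naive_pooled(
    subjects: Sequence[SubjectData],
    init: FullParams,
    err_kind: str = "combined",
    multistart: int = 4,
    seed: int = 0,
) -> FitResult:
    """Naive pooled fit of the five-parameter (V_D, F, k_abs, k_gen, CL) form.

    All subjects' observations are treated as one pseudo-subject with a
    single parameter set.  The fit is expected to be ill-conditioned: any
    common scaling of {V_D, F, k_gen, CL} leaves predictions unchanged, so
    only the ratios are identifiable.
    """
    if len(subjects) < 2:
        raise ValueError("naive pooled fit needs at least 2 subjects")
    names = list(FULL_NAMES) + (["_shape_r"] if err_kind == "combined" else [])
    x0 = np.log([getattr(init, n) for n in FULL_NAMES] + ([0.02] if err_kind == "combined" else []))
    obs = [_sorted_obs(s) for s in subjects]
    y_all = np.concatenate([y for _, y in obs])

    def _pooled_pred(p: FullParams) -> np.ndarray:
        ratios = p.to_ratios()
        return np.concatenate(
            [simulate_concentration(ratios, s.doses, t) for s, (t, _) in zip(subjects, obs)]
        )

    def objective(x):
        def nll(v):
            p = FullParams(*v[:5])
            r = v[5] if err_kind == "combined" else 0.0
            pred = _pooled_pred(p)
            err = _profiled_error(pred, y_all, err_kind, r)
            return _concentrated_nll(pred, y_all, err)

        return _safe_objective_value(nll, x)

    best, n_evals, ok = _multistart_minimize(objective, x0, multistart, seed)
    if best is None:
        return FitResult(
            estimates={n: math.nan for n in list(FULL_NAMES) + _error_param_layout(err_kind)},
            objective=math.nan,
            residuals=np.array([]),
            converged=False,
            n_function_evals=n_evals,
            message="all starts failed",
        )
    v = np.exp(best.x)
    # same flip-flop convention, expressed on the five-parameter scale
    ka, ke = v[2], v[4] / v[0]
    if ka < ke:
        v[2] = ke
        v[4] = ka * v[0]
        v[1] = v[1] * ka / ke
        v[3] = v[3] * ka / ke
    p = FullParams(*v[:5])
    pred = _pooled_pred(p)
    e = _profiled_error(pred, y_all, err_kind, v[5] if err_kind == "combined" else 0.0)
    est = {n: float(val) for n, val in zip(FULL_NAMES, v)}
    est["sigma_add"] = e.sigma_add
    est["sigma_prop"] = e.sigma_prop
    resid = np.concatenate([_weighted_residuals(s, p.to_ratios(), e) for s in subjects])
    return FitResult(
        estimates=est,
        objective=2.0 * best.fun,
        residuals=resid,
        converged=ok,
        n_function_evals=n_evals,
        message=str(best.message),
    )


def naive_pooled_condition_numbers(
    subjects: Sequence[SubjectData],
    full_fit: FitResult,
    err_kind: str = "combined",
) -> tuple[float, float]:
    """Condition numbers of the objective Hessian (log scale) at the optimum.

    Returns (cond_full, cond_ratio): the five-parameter form against the
    four-ratio form evaluated at the projected optimum.  The flat scaling
    ridge of the full form shows up as a conditioning gap of several orders
    of magnitude.
    """
    est = full_fit.estimates
    e = _build_error(err_kind, est)
    full = FullParams(**{n: est[n] for n in FULL_NAMES})
    ratio = full.to_ratios()

    def f_full(x):
        p = FullParams(**dict(zip(FULL_NAMES, np.exp(x))))
        return pooled_nll_full(subjects, p, e)

    def f_ratio(x):
        p = StructuralParams(**dict(zip(STRUCTURAL_NAMES, np.exp(x))))
        return pooled_nll_ratio(subjects, p, e)

    h_full = _numdiff.hessian(f_full, np.log([getattr(full, n) for n in FULL_NAMES]))
    h_ratio = _numdiff.hessian(f_ratio, np.log([getattr(ratio, n) for n in STRUCTURAL_NAMES]))
    return float(np.linalg.cond(h_full)), float(np.linalg.cond(h_ratio))


@dataclass
class NormalityReport:
    """Quantile-quantile summary of weighted residuals against N(0, 1)."""

    theoretical_quantiles: np.ndarray
    ordered_residuals: np.ndarray
    qq_slope: float
    shapiro_stat: float | None
    shapiro_pvalue: float | None
    tail_deviation: float
    degenerate: bool


def residual_normality_report(fit: FitResult, tail_fraction: float = 0.2) -> NormalityReport:
    """Assess normality of a fit's weighted residuals.

    Returns QQ pairs (Blom plotting positions), the least-squares QQ slope, a
    Shapiro-Wilk statistic, and a tail-deviation metric: the mean absolute
    gap between standardized ordered residuals and normal quantiles over the
    outer ``tail_fraction`` of each tail.  Smaller tail deviation means
    straighter QQ tails.
    """
    r = np.asarray(fit.residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 residuals for a normality report")
    ordered = np.sort(r)
    n = r.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    sd = float(np.std(r, ddof=1))
    if sd < 1e-12:
        return NormalityReport(theo, ordered, 0.0, None, None, math.inf, True)
    slope = float(np.sum(theo * (ordered - ordered.mean())) / np.sum(theo**2))
    sw_stat, sw_p = stats.shapiro(r)
    z = (ordered - np.mean(r)) / sd
    k = max(int(round(tail_fraction * n / 2.0)), 1)
    tails = np.r_[np.abs(z[:k] - theo[:k]), np.abs(z[-k:] - theo[-k:])]
    return NormalityReport(theo, ordered, slope, float(sw_stat), float(sw_p), float(np.mean(tails)), False)
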