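"""Declarative analysis pipeline tying the stages together.

A run is described by one config mapping (YAML file or dict): a seed, an
output directory, and an ordered stage list drawn from {simulate,
fit-individual, fit-naive-pooled, fit-pop, lrt, covariates, physio,
recover}.  Each stage writes its own CSV/JSON under the output directory,
every random seed and convergence flag is logged, and a combined text
report summarizes the parameter tables.  A stage failure halts the run
after writing a resumable state file; stages that need an upstream result
recompute it if the run is resumed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import FullParams, StructuralParams, SubjectData
from .dataio import read_dataset, write_dataset
from .inference import (
    ErrorParams,
    STRUCTURAL_NAMES,
    fit_individual,
    fit_naive_pooled,
    naive_pooled_condition_numbers,
)
from .physiology import dose_rationale
from .population import (
    PopulationModel,
    compare_nested,
    covariate_screen,
    fit_population,
    lrt_threshold,
)
from .synthetic import (
    GeneratingModel,
    TrialDesign,
    default_fit_init,
    default_generating_model,
    generate_trial,
    generator_manifest,
    recovery_experiment,
)

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = [
    "simulate",
    "fit-individual",
    "fit-naive-pooled",
    "fit-pop",
    "lrt",
    "covariates",
    "physio",
]

_VALID_STAGES = set(DEFAULT_STAGES) | {"recover"}


def _load_config(config: str | Path | dict[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and not math.isfinite(x):
        return str(x)
    return x


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


class _Context:
    """In-memory results shared between stages of one run."""

    def __init__(self, cfg: dict[str, Any], out: Path):
        self.cfg = cfg
        self.out = out
        self.seed = int(cfg.get("seed", 1))
        self.err_kind = cfg.get("error_model", "proportional")
        self.multistart = int(cfg.get("multistart", 1))
        self.subjects: list[SubjectData] | None = None
        self.pop_fit = None
        self.log: list[str] = []

    def design(self) -> TrialDesign:
        return TrialDesign(**self.cfg.get("design", {}))

    def require_subjects(self) -> list[SubjectData]:
        if self.subjects is None:
            dataset = self.cfg.get("dataset") or (self.out / "dataset.csv")
            if not Path(dataset).exists():
                raise RuntimeError("no dataset: run the simulate stage or give a dataset path")
            self.subjects = read_dataset(dataset)
            self.log.append(f"loaded dataset from {dataset}")
        return self.subjects

    def require_pop_fit(self):
        if self.pop_fit is None:
            self.pop_fit = _stage_fit_pop(self)["_fit"]
        return self.pop_fit


def _stage_simulate(ctx: _Context) -> dict:
    design = ctx.design()
    gen = default_generating_model(ctx.seed)
    subjects = generate_trial(design, gen)
    ctx.subjects = subjects
    write_dataset(subjects, ctx.out / "dataset.csv")
    manifest = generator_manifest(design, gen)
    _write_json(ctx.out / "generator_manifest.json", manifest)
    ctx.log.append(f"simulate: seed={ctx.seed}, n_subjects={design.n_subjects}")
    return {"n_subjects": design.n_subjects, "seed": ctx.seed, "converged": True}


def _stage_fit_individual(ctx: _Context) -> dict:
    subjects = ctx.require_subjects()
    init = StructuralParams(k_abs=2.0, f_over_v=0.005, cl_over_v=0.3, kgen_over_v=30.0)
    rows = []
    for s in subjects:
        fit = fit_individual(s, init, err_kind=ctx.err_kind, multistart=4, seed=ctx.seed)
        rows.append({"subject_id": s.subject_id, "converged": fit.converged, **fit.estimates})
        ctx.log.append(f"fit-individual {s.subject_id}: converged={fit.converged}")
    df = pd.DataFrame(rows)
    df.to_csv(ctx.out / "individual_fits.csv", index=False)
    summary = {
        n: {"mean": float(df[n].mean()), "sd": float(df[n].std(ddof=1)),
            "min": float(df[n].min()), "max": float(df[n].max())}
        for n in STRUCTURAL_NAMES
    }
    _write_json(ctx.out / "individual_summary.json", summary)
    return {"n_fitted": len(rows), "converged": bool(df["converged"].all()), "summary": summary}


def _stage_fit_naive_pooled(ctx: _Context) -> dict:
    subjects = ctx.require_subjects()
    init = FullParams(v_d=1.0, f=0.5, k_abs=2.0, k_gen=30.0, cl=0.3)
    fit = fit_naive_pooled(subjects, init, err_kind=ctx.err_kind, multistart=2, seed=ctx.seed)
    cond_full, cond_ratio = naive_pooled_condition_numbers(subjects, fit, err_kind=ctx.err_kind)
    out = {
        "estimates": fit.estimates,
        "ratios": {
            "f_over_v": fit.estimates["f"] / fit.estimates["v_d"],
            "cl_over_v": fit.estimates["cl"] / fit.estimates["v_d"],
            "kgen_over_v": fit.estimates["k_gen"] / fit.estimates["v_d"],
        },
        "objective": fit.objective,
        "converged": fit.converged,
        "hessian_condition_full": cond_full,
        "hessian_condition_ratio": cond_ratio,
    }
    _write_json(ctx.out / "naive_pooled.json", out)
    ctx.log.append(f"fit-naive-pooled: converged={fit.converged}, cond ratio gap="
                   f"{cond_full / max(cond_ratio, 1e-300):.2e}")
    return out


def _pop_init(ctx: _Context) -> PopulationModel:
    init = default_fit_init(ctx.err_kind)
    fix = ctx.cfg.get("fix_eta", [])
    if fix:
        omega2 = dict(init.omega2)
        fixed = dict(init.omega_fixed)
        for n in fix:
            if n not in STRUCTURAL_NAMES:
                raise ValueError(f"unknown parameter for fix_eta: {n!r}")
            omega2[n] = 0.0
            fixed[n] = True
        init = PopulationModel(init.theta, omega2, fixed, init.err)
    return init


def _stage_fit_pop(ctx: _Context) -> dict:
    subjects = ctx.require_subjects()
    fit = fit_population(
        subjects, _pop_init(ctx), multistart=ctx.multistart, seed=ctx.seed, compute_se=True
    )
    ctx.pop_fit = fit
    ranges = fit.theta_se_ranges() or {}
    table = {
        n: {
            "estimate": fit.estimates[n],
            "minus_sem": ranges.get(n, (math.nan, math.nan))[0],
            "plus_sem": ranges.get(n, (math.nan, math.nan))[1],
            "omega2": fit.model.omega2.get(n, 0.0),
            "omega_fixed": bool(fit.model.omega_fixed.get(n, False)),
            "collapsed": n in fit.collapsed,
        }
        for n in STRUCTURAL_NAMES
    }
    out = {
        "objective": fit.objective,
        "converged": fit.converged,
        "seed": ctx.seed,
        "parameters": table,
        "error": {"model_kind": fit.model.err.model_kind,
                  "sigma_add": fit.model.err.sigma_add,
                  "sigma_prop": fit.model.err.sigma_prop},
        "_fit": fit,
    }
    serializable = {k: v for k, v in out.items() if k != "_fit"}
    _write_json(ctx.out / "population_fit.json", serializable)
    pd.DataFrame(table).T.to_csv(ctx.out / "population_fit.csv")
    ctx.log.append(f"fit-pop: objective={fit.objective:.3f}, converged={fit.converged}, "
                   f"collapsed={fit.collapsed}")
    return out


def _stage_lrt(ctx: _Context) -> dict:
    subjects = ctx.require_subjects()
    small = ctx.require_pop_fit()
    theta2 = dict(small.model.theta)
    theta2["k23"] = math.log(0.01)
    theta2["k32"] = math.log(0.01)
    init_big = PopulationModel(theta2, small.model.omega2, small.model.omega_fixed, small.model.err)
    big = fit_population(subjects, init_big, multistart=1, seed=ctx.seed)
    alpha = float(ctx.cfg.get("lrt", {}).get("alpha", 0.05))
    cmp = compare_nested(small, big, extra_params=2, alpha=alpha)
    out = {
        "objective_one_compartment": small.objective,
        "objective_two_compartment": big.objective,
        "delta_objective": cmp.delta_objective,
        "threshold": cmp.threshold,
        "significant": cmp.significant,
        "shared_param_changes": cmp.shared_param_changes,
        "max_prediction_change": cmp.max_prediction_change,
        "warning": cmp.warning,
        "converged": big.converged,
    }
    _write_json(ctx.out / "lrt.json", out)
    ctx.log.append(f"lrt: delta={cmp.delta_objective:.3f} vs threshold {cmp.threshold:.2f}")
    return out


def _stage_covariates(ctx: _Context) -> dict:
    subjects = ctx.require_subjects()
    fit = ctx.require_pop_fit()
    n_perm = int(ctx.cfg.get("covariates", {}).get("n_permutations", 10_000))
    screen = covariate_screen(fit, subjects, n_permutations=n_perm, seed=ctx.seed)
    out = {"records": screen.records, "skipped": screen.skipped, "verdict": screen.verdict,
           "seed": ctx.seed, "converged": True}
    _write_json(ctx.out / "covariate_screen.json", out)
    if screen.records:
        pd.DataFrame(screen.records).to_csv(ctx.out / "covariate_screen.csv", index=False)
    ctx.log.append(f"covariates: {screen.verdict}")
    return out


def _stage_physio(ctx: _Context) -> dict:
    kwargs = dict(ctx.cfg.get("physio", {}))
    if ctx.pop_fit is not None and "kgen_over_v" not in kwargs:
        kwargs["kgen_over_v"] = ctx.pop_fit.estimates["kgen_over_v"]
    out = dose_rationale(**kwargs)
    out["converged"] = True
    _write_json(ctx.out / "dose_rationale.json", out)
    ctx.log.append("physio: dose rationale written")
    return out


def _stage_recover(ctx: _Context) -> dict:
    rec_cfg = dict(ctx.cfg.get("recover", {}))
    n_rep = int(rec_cfg.get("n_replicates", 5))
    design = ctx.design()
    gen = default_generating_model(ctx.seed)
    report = recovery_experiment(design, gen, n_replicates=n_rep, multistart=ctx.multistart)
    out = {
        "n_replicates": n_rep,
        "n_failures": report.n_failures,
        "truth": report.truth,
        "median_bias": report.median_bias,
        "relative_rmse": report.relative_rmse,
        "collapse_frequency": report.collapse_frequency,
        "converged": report.n_failures == 0,
    }
    _write_json(ctx.out / "recovery.json", out)
    ctx.log.append(f"recover: {n_rep} replicates, {report.n_failures} failures")
    return out


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit-individual": _stage_fit_individual,
    "fit-naive-pooled": _stage_fit_naive_pooled,
    "fit-pop": _stage_fit_pop,
    "lrt": _stage_lrt,
    "covariates": _stage_covariates,
    "physio": _stage_physio,
    "recover": _stage_recover,
}


def run_pipeline(config: str | Path | dict[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in order and return the report bundle.

    Stage outputs land under the output directory; ``pipeline_state.json``
    records completed stages (and the failed one, on error) so a halted run
    can be resumed.  An empty stage list is a valid no-op.
    """
    cfg = _load_config(config)
    stages: Sequence[str] = cfg.get("stages", DEFAULT_STAGES)
    unknown = [s for s in stages if s not in _VALID_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    out = Path(out_dir or cfg.get("out_dir", "serinepk_out"))
    out.mkdir(parents=True, exist_ok=True)
    ctx = _Context(cfg, out)
    state = {"completed": [], "failed": None, "seed": ctx.seed}
    results: dict[str, Any] = {"stages": {}, "seed": ctx.seed, "out_dir": str(out)}
    for stage in stages:
        try:
            res = _STAGE_FUNCS[stage](ctx)
        except Exception as exc:
            state["failed"] = {"stage": stage, "error": str(exc)}
            _write_json(out / "pipeline_state.json", state)
            raise
        results["stages"][stage] = {k: v for k, v in res.items() if not k.startswith("_")}
        state["completed"].append(stage)
        _write_json(out / "pipeline_state.json", state)
    results["log"] = ctx.log
    _write_json(out / "report.json", {k: v for k, v in results.items()})
    (out / "report.txt").write_text(_format_report(results))
    return results


def _format_report(results: dict) -> str:
    lines = [f"serinepk pipeline report (seed {results['seed']})", ""]
    for stage, res in results["stages"].items():
        lines.append(f"== {stage} ==")
        if stage == "fit-pop":
            lines.append(f"  objective (-2LL): {res['objective']:.3f}")
            lines.append(f"  {'parameter':<14}{'estimate':>12}{'-SEM':>12}{'+SEM':>12}"
                         f"{'omega2':>10}  flags")
            for n, row in res["parameters"].items():
                flags = []
                if row["omega_fixed"]:
                    flags.append("fixed")
                if row["collapsed"]:
                    flags.append("small")
                lines.append(
                    f"  {n:<14}{row['estimate']:>12.4g}{row['minus_sem']:>12.4g}"
                    f"{row['plus_sem']:>12.4g}{row['omega2']:>10.3g}  {','.join(flags)}"
                )
        elif stage == "fit-individual":
            for n, s in res["summary"].items():
                lines.append(f"  {n:<14} mean {s['mean']:.4g}  sd {s['sd']:.4g}  "
                             f"range [{s['min']:.4g}, {s['max']:.4g}]")
        elif stage == "lrt":
            lines.append(f"  delta -2LL: {res['delta_objective']:.3f} "
                         f"(threshold {res['threshold']:.2f}) -> "
                         f"{'significant' if res['significant'] else 'not significant'}")
            lines.append(f"  max typical-curve change: {res['max_prediction_change']:.2%}")
        elif stage == "covariates":
            lines.append(f"  verdict: {res['verdict']}")
        elif stage == "physio":
            plan = res["dose_plan"]
            lines.append(f"  endogenous production: {res['endogenous_production_mg_h']:.1f} mg/h "
                         f"(2 s.f. {res['endogenous_production_mg_h_2sf']:.0f})")
            lines.append(f"  hepatic fraction of oral dose: {res['total_hepatic_fraction']:.3f}")
            lines.append(f"  dose plan: {plan['daily_grams']:.1f} g/day as "
                         f"{plan['regimen_splits']} x {plan['per_administration_grams']:.1f} g")
        lines.append("")
    if not results["stages"]:
        lines.append("(no stages requested)")
    for entry in results.get("log", []):
        lines.append(f"log: {entry}")
    return "\n".join(lines) + "\n"
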