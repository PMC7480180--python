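"""End-to-end orchestration: simulate/load -> pools -> fits -> placebos ->
pooling -> costing, with a deterministic machine-readable report.

All randomness flows from a single top-level seed: the simulator consumes
it directly and each treated practice's optimiser seed is derived from it,
so rerunning with the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .costing import estimate_savings
from .errors import DonorPoolError, ScmevalError
from .inference import estimate_effects
from .meta import pool_auto
from .panel import (
    OUTCOME_COLUMNS,
    InterventionSchedule,
    build_donor_pool,
    load_panel,
    outcome_wide,
    panel_months,
)
from .scm import DEFAULT_COVARIATES, FitSettings, PredictorSpec
from .simulate import SimConfig, generate_panel

log = logging.getLogger("scmeval")

OUTCOME_LABELS = {
    "ed_rate": "ED attendances",
    "adm_rate": "Unplanned admissions",
    "readm_rate": "Unplanned readmissions",
}


def default_config() -> dict:
    """Demo configuration: simulated programme of 10 practices, 40 donors."""
    return {
        "seed": 0,
        "data": {
            "mode": "simulate",
            "panel_path": None,
            "schedule_path": None,
            "simulate": {},  # overrides for SimConfig fields
        },
        "donors": {"tolerance": 0.20, "group_col": None, "min_pool": 12, "max_tolerance": 0.9},
        "scm": {
            "covariates": list(DEFAULT_COVARIATES),
            "outcomes": list(OUTCOME_COLUMNS),
            "standardize": True,
            "multistarts": 5,
            "nm_maxiter": 150,
            "mspe_cap": None,
        },
        "inference": {"min_placebos": 10, "mspe_ratio_cap": None},
        "pooling": {"alpha": 0.05},
        "costing": {
            "outcome": "adm_rate",
            "population": 67402,
            "reference_cost": 1603.0,
            "fce": 20_000_000,
            "fae": 16_600_000,
        },
    }


def load_config(path) -> dict:
    """Read a YAML config, filling unspecified sections with defaults."""
    user = yaml.safe_load(Path(path).read_text()) or {}
    config = default_config()
    for section, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(section), dict):
            config[section].update(value)
        else:
            config[section] = value
    return config


def _get_inputs(config: dict) -> tuple[pd.DataFrame, InterventionSchedule, int]:
    data = config["data"]
    seed = int(config["seed"])
    if data.get("mode", "simulate") == "simulate":
        overrides = dict(data.get("simulate") or {})
        overrides.setdefault("seed", seed)
        for key in ("outcome_means", "outcome_sds", "noise_sd", "treatment_effects",
                    "list_size_range", "join_months"):
            if key in overrides and overrides[key] is not None:
                overrides[key] = tuple(overrides[key])
        sim = SimConfig(**overrides)
        panel, schedule = generate_panel(sim)
        return panel, schedule, seed
    panel = load_panel(data["panel_path"])
    schedule = InterventionSchedule.from_yaml(data["schedule_path"])
    return panel, schedule, seed


def _pool_with_backoff(panel, schedule, treated_id, donors_cfg, warnings_list):
    """Build a donor pool, widening the list-size band if it is too small.

    The +/-20% band is the study constraint; at small donor counts it can
    leave too few placebos for inference, so the tolerance is relaxed in
    0.05 steps (up to ``max_tolerance``) with each widening logged in the
    report warnings.
    """
    tolerance = float(donors_cfg.get("tolerance", 0.20))
    min_pool = int(donors_cfg.get("min_pool", 12))
    max_tol = float(donors_cfg.get("max_tolerance", 0.5))
    group_col = donors_cfg.get("group_col")
    while True:
        try:
            pool = build_donor_pool(panel, schedule, treated_id,
                                    tolerance=tolerance, group_col=group_col)
        except DonorPoolError:
            pool = None
        if pool is not None and len(pool.donor_ids) >= min_pool:
            return pool, tolerance
        if tolerance + 0.05 > max_tol + 1e-9:
            if pool is None:
                raise DonorPoolError(
                    f"no donors for {treated_id!r} even at tolerance {tolerance:.2f}"
                )
            return pool, tolerance  # accept a small pool rather than fail
        tolerance = round(tolerance + 0.05, 10)
        warnings_list.append(
            f"{treated_id}: donor pool below {min_pool}, widened list-size "
            f"tolerance to {tolerance:.2f}"
        )


def run_all(config, out_dir: Optional[str] = None) -> dict:
    """Execute the full pipeline and return the run report (a plain dict).

    ``config`` may be a dict or a YAML path.  When ``out_dir`` is given the
    panel, schedule, report JSON and a human-readable summary are written
    there.  Identical config (including seed) regenerates the report
    byte-identically.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = copy.deepcopy(config)

    panel, schedule, seed = _get_inputs(config)
    first_month, last_month = panel_months(panel)

    scm_cfg = config["scm"]
    spec = PredictorSpec(
        covariate_names=tuple(scm_cfg["covariates"]),
        outcome_names=tuple(scm_cfg["outcomes"]),
        standardize=bool(scm_cfg.get("standardize", True)),
    )
    inf_cfg = config["inference"]

    warnings_list: list[str] = []
    seed_registry = {"master": seed}
    fits_report: dict[str, dict] = {}
    effects_by_outcome: dict[str, list] = {o: [] for o in spec.outcome_names}
    effects_report: dict[str, dict] = {}

    for idx, treated_id in enumerate(schedule.treated_ids):
        stage = f"donor_pool[{treated_id}]"
        try:
            pool, used_tol = _pool_with_backoff(
                panel, schedule, treated_id, config["donors"], warnings_list
            )
            stage = f"fit+placebo[{treated_id}]"
            fit_seed = (seed * 1000 + idx) % (2**31 - 1)
            seed_registry[treated_id] = fit_seed
            settings = FitSettings(
                n_multistarts=int(scm_cfg.get("multistarts", 5)),
                nm_maxiter=int(scm_cfg.get("nm_maxiter", 150)),
                seed=fit_seed,
                mspe_cap=scm_cfg.get("mspe_cap"),
            )
            join = schedule.join_month(treated_id)
            _, post_end = schedule.post_window(treated_id, last_month)
            fit, estimates, failures = estimate_effects(
                panel,
                pool,
                spec,
                join,
                post_end=post_end,
                settings=settings,
                min_placebos=int(inf_cfg.get("min_placebos", 10)),
                mspe_ratio_cap=inf_cfg.get("mspe_ratio_cap"),
            )
        except ScmevalError as exc:
            raise ScmevalError(f"stage {stage} failed: {exc}") from exc

        for donor, reason in failures.items():
            warnings_list.append(f"{treated_id}: placebo {donor} dropped ({reason})")
        fits_report[treated_id] = {
            "join_month": join,
            "post_end": post_end,
            "donor_pool_size": len(pool.donor_ids),
            "list_size_tolerance": used_tol,
            "weights": {k: round(v, 8) for k, v in fit.weights(threshold=1e-6).items()},
            "pre_mspe": {k: round(v, 10) for k, v in fit.pre_mspe.items()},
            "objective": round(fit.objective, 10),
        }
        effects_report[treated_id] = {}
        for outcome, est in estimates.items():
            effects_by_outcome[outcome].append(est)
            effects_report[treated_id][outcome] = {
                "delta": round(est.delta, 8),
                "se": round(est.se, 8),
                "ci95": [round(est.ci95[0], 8), round(est.ci95[1], 8)],
                "p": round(est.p, 8),
                "n_placebos": int(est.placebo_deltas.size),
            }

    pooled_report: dict[str, dict] = {}
    pooled_objects = {}
    alpha = float(config["pooling"].get("alpha", 0.05))
    for outcome in spec.outcome_names:
        pooled = pool_auto(effects_by_outcome[outcome], alpha=alpha)
        pooled_objects[outcome] = pooled
        pooled_report[outcome] = {
            "delta_pooled": round(pooled.delta_pooled, 8),
            "se_pooled": round(pooled.se_pooled, 8),
            "ci95": [round(pooled.ci95[0], 8), round(pooled.ci95[1], 8)],
            "p": round(pooled.p, 8),
            "Q": round(pooled.Q, 8),
            "df": pooled.df,
            "q_p": round(pooled.q_p, 8),
            "i2_pct": round(pooled.i2, 4),
            "i2_ci95_pct": [round(pooled.i2_ci95[0], 4), round(pooled.i2_ci95[1], 4)],
            "tau2": round(pooled.tau2, 10),
            "model": pooled.model,
            "k": pooled.k,
        }

    cost_cfg = config["costing"]
    cost_report = None
    cost_outcome = cost_cfg.get("outcome")
    if cost_outcome and cost_outcome in pooled_objects:
        pooled = pooled_objects[cost_outcome]
        result = estimate_savings(
            pooled.delta_pooled,
            pooled.ci95,
            int(cost_cfg["population"]),
            float(cost_cfg["reference_cost"]),
            float(cost_cfg["fce"]),
            float(cost_cfg["fae"]),
        )
        cost_report = {
            "outcome": cost_outcome,
            "population": result.population,
            "effect": round(result.effect, 8),
            "monthly_events": result.monthly_events,
            "annual_events": result.annual_events,
            "unit_cost": result.unit_cost,
            "savings": result.savings,
            "savings_lo": result.savings_lo,
            "savings_hi": result.savings_hi,
        }

    report = {
        "config": config,
        "panel": {
            "n_practices": int(panel["practice_id"].nunique()),
            "n_months": last_month - first_month + 1,
            "n_treated": len(schedule.treated_ids),
        },
        "fits": fits_report,
        "effects": effects_report,
        "pooled": pooled_report,
        "cost": cost_report,
        "warnings": warnings_list,
        "seeds": seed_registry,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        panel.to_csv(out / "panel.csv", index=False)
        schedule.to_yaml(out / "schedule.yaml")
        write_report(report, out / "report.json")
        (out / "summary.txt").write_text(summary_table(report))
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def summary_table(report: dict) -> str:
    """Forest-plot-style text summary of per-practice and pooled effects."""
    lines = []
    for outcome, pooled in report["pooled"].items():
        label = OUTCOME_LABELS.get(outcome, outcome)
        lines.append(f"{label} (per 100 patients per month)")
        lines.append(f"  {'practice':<12}{'effect':>10}{'95% CI':>22}{'p':>10}")
        for pid, eff in report["effects"].items():
            e = eff[outcome]
            ci = f"({e['ci95'][0]:+.3f}, {e['ci95'][1]:+.3f})"
            lines.append(f"  {pid:<12}{e['delta']:>+10.3f}{ci:>22}{e['p']:>10.4f}")
        ci = f"({pooled['ci95'][0]:+.3f}, {pooled['ci95'][1]:+.3f})"
        lines.append(
            f"  {'POOLED(' + pooled['model'] + ')':<12}{pooled['delta_pooled']:>+10.3f}"
            f"{ci:>22}{pooled['p']:>10.4f}"
        )
        lines.append(
            f"  I2 = {pooled['i2_pct']:.1f}% "
            f"(95% CI {pooled['i2_ci95_pct'][0]:.1f}% to {pooled['i2_ci95_pct'][1]:.1f}%), "
            f"df = {pooled['df']}, Q-test p = {pooled['q_p']:.2f}"
        )
        lines.append("")
    cost = report.get("cost")
    if cost:
        label = OUTCOME_LABELS.get(cost["outcome"], cost["outcome"])
        lines.append(
            f"{label}: {cost['monthly_events']} avoided events/month "
            f"({cost['annual_events']}/year) x unit cost {cost['unit_cost']} "
            f"= {cost['savings']} per annum "
            f"(CI-bound sensitivity: {cost['savings_lo']} / {cost['savings_hi']})"
        )
    return "\n".join(lines) + "\n"


def plot_paths(report: dict, panel: pd.DataFrame, outcome: str, path) -> None:
    """Per-practice treated-vs-synthetic line plots with shaded pre-period."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if outcome not in report["pooled"]:
        raise ScmevalError(f"unknown outcome {outcome!r}")
    fits = report["fits"]
    n = len(fits)
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 2.8 * nrows),
                             squeeze=False, sharex=True)
    wide = outcome_wide(panel, outcome)
    months = wide.index.to_numpy()
    for ax, (pid, fit) in zip(axes.ravel(), fits.items()):
        weights = fit["weights"]
        sc = sum(w * wide[donor].to_numpy() for donor, w in weights.items())
        ax.axvspan(months.min(), fit["join_month"] - 1, color="0.9")
        ax.plot(months, wide[pid].to_numpy(), label="treated", lw=1.2)
        ax.plot(months, sc, label="synthetic control", lw=1.2, ls="--")
        ax.set_title(pid, fontsize=9)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    axes[0, 0].legend(fontsize=8)
    fig.suptitle(OUTCOME_LABELS.get(outcome, outcome))
    fig.supxlabel("month")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
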