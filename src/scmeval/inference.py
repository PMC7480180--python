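"""Per-practice effect estimation with placebo-based inference.

The causal estimand per practice and outcome is a difference-in-differences
on monthly rates: the change from the pre-intervention mean to the
post-intervention mean in the treated practice, minus the same change in
its synthetic control, in units of events per 100 registered patients per
month.

Uncertainty comes from placebo tests: the full synthetic-control fit is
repeated with each donor cast as a pseudo-treated unit (its pool being the
remaining donors) at the same join month.  The spread of the resulting
placebo effects estimates the sampling variability of the treated effect
under no intervention; the standard error is their sample SD and p-values /
confidence intervals use a normal approximation, which is what allows the
per-practice effects to be pooled by inverse variance downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, PlaceboError
from .panel import DonorPool, panel_months
from .scm import (
    FitSettings,
    PredictorSpec,
    ScmFit,
    assemble_matrices,
    fit_from_matrices,
    make_wide_cache,
)


def did_effect(
    treated_path: pd.Series,
    sc_path: pd.Series,
    pre_window: tuple[int, int],
    post_window: tuple[int, int],
) -> float:
    """Difference-in-differences of window means between a practice and its SC.

    ``delta = [mean(treated, post) - mean(treated, pre)]
            - [mean(sc, post) - mean(sc, pre)]``.

    Paths are series indexed by month; both windows are inclusive and must
    be non-empty.
    """
    def window_mean(path: pd.Series, window: tuple[int, int]) -> float:
        lo, hi = window
        values = path.loc[(path.index >= lo) & (path.index <= hi)]
        if values.empty:
            raise FitError(f"window {window} selects no months")
        return float(values.mean())

    return (window_mean(treated_path, post_window) - window_mean(treated_path, pre_window)) - (
        window_mean(sc_path, post_window) - window_mean(sc_path, pre_window)
    )


@dataclass
class EffectEstimate:
    """One practice x outcome effect with placebo-derived uncertainty."""

    treated_id: str
    outcome: str
    delta: float
    se: float
    ci95: tuple[float, float]
    p: float
    placebo_deltas: np.ndarray
    pre_mspe_treated: float


def infer_effect(
    delta: float,
    placebo_deltas: Sequence[float],
    treated_id: str = "",
    outcome: str = "",
    pre_mspe_treated: float = float("nan"),
    min_placebos: int = 10,
) -> EffectEstimate:
    """Turn a treated effect and its placebo distribution into an estimate.

    SE is the sample standard deviation of the placebo effects; the 95% CI
    is ``delta +/- 1.96 se`` and the two-sided p-value uses the standard
    normal distribution.
    """
    placebo_deltas = np.asarray(placebo_deltas, dtype=float)
    if placebo_deltas.size < min_placebos:
        raise PlaceboError(
            f"only {placebo_deltas.size} placebo effects (< {min_placebos}); "
            "inference would be unreliable"
        )
    se = float(np.std(placebo_deltas, ddof=1))
    if se <= 1e-12 * max(1.0, float(np.abs(placebo_deltas).max())):
        raise PlaceboError("placebo effects have zero spread; degenerate null distribution")
    p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return EffectEstimate(
        treated_id=treated_id,
        outcome=outcome,
        delta=float(delta),
        se=se,
        ci95=(float(delta - 1.96 * se), float(delta + 1.96 * se)),
        p=p,
        placebo_deltas=placebo_deltas,
        pre_mspe_treated=float(pre_mspe_treated),
    )


def _fit_and_deltas(
    panel: pd.DataFrame,
    pool: DonorPool,
    spec: PredictorSpec,
    pre_window: tuple[int, int],
    post_window: tuple[int, int],
    settings: FitSettings,
    wides=None,
) -> tuple[ScmFit, dict[str, float]]:
    if wides is None:
        wides = make_wide_cache(panel, spec)
    mats = assemble_matrices(panel, pool, spec, pre_window, wides=wides)
    fit = fit_from_matrices(mats, settings)
    deltas = {}
    for outcome in spec.outcome_names:
        wide = wides[outcome]
        treated_path = wide[pool.treated_id]
        sc_path = pd.Series(wide[pool.donor_ids].to_numpy() @ fit.W, index=wide.index)
        deltas[outcome] = did_effect(treated_path, sc_path, pre_window, post_window)
    return fit, deltas


def run_placebos(
    panel: pd.DataFrame,
    pool: DonorPool,
    spec: PredictorSpec,
    join_month: int,
    post_end: Optional[int] = None,
    settings: FitSettings = FitSettings(),
    min_placebos: int = 10,
    mspe_ratio_cap: Optional[float] = None,
    treated_pre_mspe: Optional[float] = None,
    wides=None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Refit the synthetic control with each donor as pseudo-treated unit.

    Each donor ``j`` is fitted against the pool minus ``j`` (never against
    itself) using the treated practice's join month and windows, and its
    DiD effect per outcome is recorded.  Donors whose fit raises are dropped
    and logged; with ``mspe_ratio_cap`` set, placebos whose pre-period MSPE
    exceeds ``cap x treated_pre_mspe`` are excluded as poorly fitting.

    Returns a (donor x outcome) frame of placebo effects plus a log of
    exclusions; raises :class:`PlaceboError` when fewer than
    ``min_placebos`` placebos survive.
    """
    first_month, last_month = panel_months(panel)
    pre_window = (first_month, join_month - 1)
    post_window = (join_month, post_end if post_end is not None else last_month)
    if wides is None:
        wides = make_wide_cache(panel, spec)

    records: dict[str, dict[str, float]] = {}
    failures: dict[str, str] = {}
    for j in pool.donor_ids:
        sub_pool = DonorPool(
            treated_id=j,
            donor_ids=[d for d in pool.donor_ids if d != j],
            constraint_log={},
        )
        try:
            fit_j, deltas = _fit_and_deltas(
                panel, sub_pool, spec, pre_window, post_window, settings, wides=wides
            )
        except Exception as exc:
            failures[j] = f"fit failed: {exc}"
            continue
        if (
            mspe_ratio_cap is not None
            and treated_pre_mspe is not None
            and treated_pre_mspe > 0
            and fit_j.objective > mspe_ratio_cap * treated_pre_mspe
        ):
            failures[j] = (
                f"pre-MSPE {fit_j.objective:.4g} > {mspe_ratio_cap} x treated "
                f"{treated_pre_mspe:.4g}"
            )
            continue
        records[j] = deltas

    if len(records) < min_placebos:
        raise PlaceboError(
            f"only {len(records)} successful placebo fits (< {min_placebos}) "
            f"for treated {pool.treated_id!r}"
        )
    placebo_df = pd.DataFrame.from_dict(records, orient="index")[list(spec.outcome_names)]
    return placebo_df, failures


def estimate_effects(
    panel: pd.DataFrame,
    pool: DonorPool,
    spec: PredictorSpec,
    join_month: int,
    post_end: Optional[int] = None,
    settings: FitSettings = FitSettings(),
    min_placebos: int = 10,
    mspe_ratio_cap: Optional[float] = None,
) -> tuple[ScmFit, dict[str, EffectEstimate], dict[str, str]]:
    """Fit the treated practice, run its placebos and infer all effects."""
    first_month, last_month = panel_months(panel)
    pre_window = (first_month, join_month - 1)
    post_window = (join_month, post_end if post_end is not None else last_month)
    wides = make_wide_cache(panel, spec)
    fit, deltas = _fit_and_deltas(
        panel, pool, spec, pre_window, post_window, settings, wides=wides
    )
    placebo_df, failures = run_placebos(
        panel,
        pool,
        spec,
        join_month,
        post_end=post_end,
        settings=settings,
        min_placebos=min_placebos,
        mspe_ratio_cap=mspe_ratio_cap,
        treated_pre_mspe=fit.objective,
        wides=wides,
    )
    estimates = {
        outcome: infer_effect(
            deltas[outcome],
            placebo_df[outcome].to_numpy(),
            treated_id=pool.treated_id,
            outcome=outcome,
            pre_mspe_treated=fit.pre_mspe[outcome],
            min_placebos=min_placebos,
        )
        for outcome in spec.outcome_names
    }
    return fit, estimates, failures
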