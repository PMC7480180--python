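"""Synthetic monthly GP-practice panels with injectable treatment effects.

The generator emulates the statistical structure the synthetic-control
estimator assumes: an interactive fixed-effects (latent factor) outcome
model with practice intercepts, a shared smooth time factor with
practice-specific loadings, sinusoidal seasonality and Gaussian month-level
noise.  Deprivation-like covariates are drawn correlated with the outcome
intercepts so that covariate matching is informative.

Rates are generated per 100 registered patients per month and clipped at
zero.  Default calibration targets a pooled pre-intervention profile of
roughly 2.7 ED attendances, 0.87 unplanned admissions and 0.12 unplanned
readmissions per 100 patients per month over a 48-month panel, with join
months staggered through the middle of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .panel import (
    COVARIATE_COLUMNS,
    OUTCOME_COLUMNS,
    PANEL_COLUMNS,
    InterventionSchedule,
    validate_panel,
)

#: Join months used when ten practices adopt: three joins at month 15 then a
#: staggered tail through month 40, mirroring a programme that ramps up over
#: two years of a four-year panel.
STAGGERED_JOINS_10 = (15, 15, 15, 22, 25, 28, 30, 32, 35, 40)


def _default_joins(n_treated: int, n_months: int) -> tuple[int, ...]:
    if n_treated == 10 and n_months >= 41:
        return STAGGERED_JOINS_10
    lo, hi = max(2, n_months // 3), min(n_months - 6, int(0.85 * n_months))
    hi = max(hi, lo)
    return tuple(int(round(x)) for x in np.linspace(lo, hi, n_treated))


@dataclass(frozen=True)
class SimConfig:
    """Calibration of the synthetic panel generator.

    Outcome means/SDs are per 100 patients per month; ``outcome_sds`` is the
    between-practice spread of the intercepts and ``noise_sd`` the
    month-level noise.  ``treatment_effects`` are additive shifts applied to
    treated practices from their join month onwards (negative = reduction).
    """

    n_treated: int = 10
    n_donors: int = 40
    n_months: int = 48
    outcome_means: tuple[float, float, float] = (2.70, 0.87, 0.12)
    outcome_sds: tuple[float, float, float] = (0.55, 0.20, 0.040)
    factor_loading_sd: float = 0.30
    factor_scale: float = 0.05
    seasonal_amplitude: float = 0.08
    treatment_effects: tuple[float, float, float] = (0.0, -0.11, -0.021)
    join_months: Optional[Sequence[int]] = None
    list_size_range: tuple[int, int] = (4000, 10000)
    noise_sd: tuple[float, float, float] = (0.28, 0.11, 0.038)
    count_mode: bool = False
    seed: int = 0

    def resolved_joins(self) -> tuple[int, ...]:
        joins = (
            tuple(int(j) for j in self.join_months)
            if self.join_months is not None
            else _default_joins(self.n_treated, self.n_months)
        )
        if len(joins) != self.n_treated:
            raise ConfigError(
                f"join_months has {len(joins)} entries for {self.n_treated} treated practices"
            )
        return joins

    def validate(self) -> None:
        if self.n_months < 2:
            raise ConfigError("n_months must be at least 2")
        if self.n_treated < 1 or self.n_donors < 1:
            raise ConfigError("need at least one treated and one donor practice")
        if any(m <= 0 for m in self.outcome_means):
            raise ConfigError("all outcome rate means must be positive")
        lo, hi = self.list_size_range
        if not (0 < lo < hi):
            raise ConfigError("list_size_range must be positive and increasing")
        for j in self.resolved_joins():
            if not 1 < j < self.n_months:
                raise ConfigError(
                    f"join month {j} must lie strictly inside (1, {self.n_months})"
                )
        # Reject calibrations that would clip a material share of draws at 0:
        # with > 10% of the mass below zero the clipped panel no longer has the
        # configured means and the factor structure degrades.
        for o, mean in enumerate(self.outcome_means):
            total_var = (
                self.outcome_sds[o] ** 2
                + self.noise_sd[o] ** 2
                + (self.factor_scale * mean) ** 2 * (1.0 + self.factor_loading_sd**2)
                + 0.5 * (self.seasonal_amplitude * mean) ** 2
            )
            p_clip = float(stats.norm.cdf(-mean / np.sqrt(total_var)))
            if p_clip > 0.10:
                raise ConfigError(
                    f"outcome {OUTCOME_COLUMNS[o]!r}: calibration clips "
                    f"{100 * p_clip:.1f}% of draws at zero (>10%); "
                    "raise the mean or reduce the spread"
                )


def _smooth_factor(rng: np.random.Generator, n_months: int) -> np.ndarray:
    """Shared smooth time factor, standardised to mean 0 / SD 1."""
    raw = rng.standard_normal(n_months + 8)
    window = np.hanning(9)
    smooth = np.convolve(raw, window / window.sum(), mode="same")[4:-4]
    smooth = smooth - smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _draw_covariates(rng, n, z, list_sizes):
    """Time-constant covariates; deprivation-like ones track the latent z."""
    cov = {}
    cov["gp_count"] = np.maximum(1, np.round(list_sizes / 1800 + rng.normal(0, 1.0, n)))
    cov["nurse_count"] = np.maximum(1, np.round(list_sizes / 3200 + rng.normal(0, 0.8, n)))
    cov["bme_pct"] = np.clip(25 + 12 * z + rng.normal(0, 8, n), 0, 95)
    cov["imd"] = np.clip(28 + 8 * z + rng.normal(0, 4, n), 1, 80)
    cov["urban_pct"] = np.clip(90 + rng.normal(0, 6, n), 0, 100)
    bands = {
        "female_0_19_pct": 11.0,
        "female_20_64_pct": 29.0,
        "female_65_plus_pct": 10.0,
        "male_0_19_pct": 12.0,
        "male_20_64_pct": 30.0,
        "male_65_plus_pct": 8.0,
    }
    for name, base in bands.items():
        cov[name] = np.clip(base + rng.normal(0, 1.5, n), 0, 60)
    cov["ltc_prev"] = np.clip(20 + 4 * z + rng.normal(0, 2.0, n), 0, 100)
    cov["diabetes_prev"] = np.clip(7 + 1.5 * z + rng.normal(0, 1.0, n), 0, 100)
    return cov


def generate_panel(config: SimConfig) -> tuple[pd.DataFrame, InterventionSchedule]:
    """Draw one rectangular panel plus its staggered intervention schedule.

    Outcome model per practice i, outcome o, month t (1-based)::

        rate = max(0, alpha[i,o] + seasonal_o(t) + gamma[i] * f(t) * c_o
                      + delta_o * post[i,t] + eps[i,o,t])

    with ``alpha`` the practice intercepts (correlated across outcomes via a
    latent deprivation axis), ``f`` a shared smooth standardised factor,
    ``gamma ~ N(1, factor_loading_sd)``, ``c_o = factor_scale * mean_o`` and
    ``eps ~ N(0, noise_sd_o)``.  Identical config (including seed) gives a
    bit-identical panel.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    joins = config.resolved_joins()

    n = config.n_treated + config.n_donors
    width = len(str(max(config.n_treated, config.n_donors)))
    treated_ids = [f"T{k + 1:0{width}d}" for k in range(config.n_treated)]
    donor_ids = [f"D{k + 1:0{width}d}" for k in range(config.n_donors)]
    practice_ids = treated_ids + donor_ids

    lo, hi = config.list_size_range
    mid, spread = 0.5 * (lo + hi), (hi - lo) / 6.0
    list_sizes = np.clip(rng.normal(mid, spread, n), lo, hi).round()

    # Latent deprivation axis shared by intercepts and covariates.
    z = rng.standard_normal(n)
    rho = 0.6
    alpha = np.empty((n, 3))
    for o in range(3):
        u = rng.standard_normal(n)
        alpha[:, o] = config.outcome_means[o] + config.outcome_sds[o] * (
            rho * z + np.sqrt(1 - rho**2) * u
        )
    gamma = rng.normal(1.0, config.factor_loading_sd, n)
    factor = _smooth_factor(rng, config.n_months)
    months = np.arange(1, config.n_months + 1)
    season = np.sin(2 * np.pi * (months - 1) / 12.0)

    covariates = _draw_covariates(rng, n, z, list_sizes)
    em_los_base = np.clip(5.0 + 0.5 * z + rng.normal(0, 0.4, n), 0.5, None)

    post = np.zeros((n, config.n_months), dtype=bool)
    schedule_entries = {}
    for i, pid in enumerate(treated_ids):
        post[i, joins[i] - 1 :] = True
        schedule_entries[pid] = (joins[i], None)

    rows = {c: [] for c in PANEL_COLUMNS}
    rates = np.empty((n, config.n_months, 3))
    for o, mean in enumerate(config.outcome_means):
        eps = rng.normal(0, config.noise_sd[o], (n, config.n_months))
        base = (
            alpha[:, o][:, None]
            + config.seasonal_amplitude * mean * season[None, :]
            + gamma[:, None] * factor[None, :] * (config.factor_scale * mean)
            + config.treatment_effects[o] * post
            + eps
        )
        rates[:, :, o] = np.maximum(0.0, base)
        if config.count_mode:
            lam = rates[:, :, o] * list_sizes[:, None] / 100.0
            events = rng.poisson(np.maximum(lam, 0.0))
            rates[:, :, o] = 100.0 * events / list_sizes[:, None]

    em_los_noise = rng.normal(0, 0.6, (n, config.n_months))
    em_los = np.maximum(0.0, em_los_base[:, None] + em_los_noise)

    for i, pid in enumerate(practice_ids):
        rows["practice_id"].extend([pid] * config.n_months)
        rows["month_index"].extend(months.tolist())
        rows["list_size"].extend([list_sizes[i]] * config.n_months)
        for o, col in enumerate(OUTCOME_COLUMNS):
            rows[col].extend(rates[i, :, o].tolist())
        rows["em_los"].extend(em_los[i].tolist())
        for col in COVARIATE_COLUMNS:
            rows[col].extend([covariates[col][i]] * config.n_months)

    panel = validate_panel(pd.DataFrame(rows))
    return panel, InterventionSchedule(schedule_entries)


def inject_effect(
    panel: pd.DataFrame,
    schedule: InterventionSchedule,
    effects: tuple[float, float, float],
) -> pd.DataFrame:
    """Add post-period effects to treated practices' outcome rates.

    For each scheduled practice, every month from its join month to the
    month before any exit has ``effects[o]`` added to outcome ``o``, clipped
    at zero.  Donor rows are untouched; the input frame is not modified.
    """
    missing = [pid for pid in schedule.entries if pid not in set(panel["practice_id"])]
    if missing:
        raise ConfigError(f"scheduled practices absent from panel: {missing}")
    out = panel.copy()
    n_months = int(panel["month_index"].max())
    for pid, (join, exit_month) in schedule.entries.items():
        end = n_months if exit_month is None else exit_month - 1
        mask = (
            (out["practice_id"] == pid)
            & (out["month_index"] >= join)
            & (out["month_index"] <= end)
        )
        for o, col in enumerate(OUTCOME_COLUMNS):
            out.loc[mask, col] = np.maximum(0.0, out.loc[mask, col] + effects[o])
    return out


def null_config(config: SimConfig) -> SimConfig:
    """Same calibration with all treatment effects set to zero."""
    return replace(config, treatment_effects=(0.0, 0.0, 0.0))
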