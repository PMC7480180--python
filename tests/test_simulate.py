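"""Generator contract: determinism, calibration, effect injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scmeval.errors import ConfigError
from scmeval.panel import OUTCOME_COLUMNS, InterventionSchedule
from scmeval.simulate import SimConfig, generate_panel, inject_effect, null_config

from conftest import build_panel


def test_same_seed_is_bit_identical(small_config):
    panel_a, sched_a = generate_panel(small_config)
    panel_b, sched_b = generate_panel(small_config)
    pd.testing.assert_frame_equal(panel_a, panel_b)
    assert sched_a.entries == sched_b.entries


def test_panel_is_rectangular_and_nonnegative(small_panel, small_config):
    panel, schedule = small_panel
    counts = panel.groupby("practice_id")["month_index"].nunique()
    assert (counts == small_config.n_months).all()
    assert len(counts) == small_config.n_treated + small_config.n_donors
    for col in OUTCOME_COLUMNS:
        assert (panel[col] >= 0).all()
    assert set(schedule.treated_ids) <= set(panel["practice_id"])


def test_null_effect_means_match_between_groups(small_config):
    """With no injected effect, treated and donor post-period outcome means
    differ only by sampling noise (two-sample t-test at alpha=0.01)."""
    rejections = 0
    for seed in range(20):
        cfg = null_config(small_config)
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
        panel, schedule = generate_panel(cfg)
        first_join = min(j for j, _ in schedule.entries.values())
        post = panel[panel["month_index"] >= first_join]
        means = post.groupby("practice_id")["adm_rate"].mean()
        treated = means[means.index.isin(schedule.entries)]
        donors = means[~means.index.isin(schedule.entries)]
        _, p = stats.ttest_ind(treated, donors, equal_var=False)
        rejections += p < 0.01
    assert rejections <= 2


def test_default_calibration_matches_admission_rate_target():
    """Pooled pre-period admission rate sits near 0.87 per 100 per month."""
    means = []
    for seed in range(10):
        cfg = SimConfig(seed=seed)
        panel, schedule = generate_panel(cfg)
        pre_means = []
        for pid, (join, _) in schedule.entries.items():
            rows = panel[(panel["practice_id"] == pid) & (panel["month_index"] < join)]
            pre_means.append(rows["adm_rate"].mean())
        means.append(np.mean(pre_means))
    assert abs(np.mean(means) - 0.87) < 0.15


def test_degenerate_config_reproduces_treated_series_exactly():
    """No noise, no loading spread, no intercept spread: every donor's series
    equals the treated pre-period series, and the injected effect appears as
    an exact post-period shift."""
    cfg = SimConfig(
        n_treated=1,
        n_donors=3,
        n_months=24,
        join_months=(13,),
        outcome_sds=(0.0, 0.0, 0.0),
        factor_loading_sd=0.0,
        noise_sd=(0.0, 0.0, 0.0),
        treatment_effects=(0.0, -0.11, 0.0),
        seed=2,
    )
    panel, schedule = generate_panel(cfg)
    wide = panel.pivot(index="month_index", columns="practice_id", values="adm_rate")
    treated = schedule.treated_ids[0]
    donors = [c for c in wide.columns if c != treated]
    pre = wide.index < 13
    for d in donors:
        np.testing.assert_allclose(wide.loc[pre, treated], wide.loc[pre, d], atol=1e-12)
        np.testing.assert_allclose(
            wide.loc[~pre, treated], wide.loc[~pre, d] - 0.11, atol=1e-12
        )


def test_inject_effect_identity_and_arithmetic():
    panel = build_panel({f"P{i}": {} for i in range(3)}, n_months=48)
    schedule = InterventionSchedule({"P0": (25, None)})

    unchanged = inject_effect(panel, schedule, (0.0, 0.0, 0.0))
    pd.testing.assert_frame_equal(unchanged, panel)

    shifted = inject_effect(panel, schedule, (0.0, -0.11, 0.0))
    out = shifted.set_index(["practice_id", "month_index"])["adm_rate"]
    base = panel.set_index(["practice_id", "month_index"])["adm_rate"]
    for month in range(1, 49):
        expected = 0.89 if month >= 25 else 1.0
        assert out.loc[("P0", month)] == pytest.approx(expected)
        assert out.loc[("P1", month)] == base.loc[("P1", month)]


def test_inject_effect_clips_at_zero():
    panel = build_panel({"P0": {}, "P1": {}}, n_months=48)
    schedule = InterventionSchedule({"P0": (25, None)})
    shifted = inject_effect(panel, schedule, (0.0, -5.0, 0.0))
    post = shifted[(shifted["practice_id"] == "P0") & (shifted["month_index"] >= 25)]
    assert (post["adm_rate"] == 0.0).all()


def test_inject_effect_respects_exit_month():
    panel = build_panel({"P0": {}, "P1": {}}, n_months=48)
    schedule = InterventionSchedule({"P0": (25, 40)})
    shifted = inject_effect(panel, schedule, (0.0, -0.5, 0.0))
    rates = shifted[shifted["practice_id"] == "P0"].set_index("month_index")["adm_rate"]
    assert rates.loc[39] == pytest.approx(0.5)
    assert rates.loc[40] == pytest.approx(1.0)  # exited: no effect applied


@pytest.mark.parametrize(
    "overrides",
    [
        {"n_months": 1},
        {"outcome_means": (0.0, 0.87, 0.12)},
        {"join_months": (1, 16, 20)},
        {"join_months": (12, 16, 30)},
        {"list_size_range": (8000, 4000)},
        # heavy clipping: mean far below the draw spread
        {"outcome_means": (2.7, 0.87, 0.02), "noise_sd": (0.28, 0.11, 0.1)},
    ],
)
def test_invalid_configs_are_rejected(small_config, overrides):
    cfg = SimConfig(**{**small_config.__dict__, **overrides})
    with pytest.raises(ConfigError):
        cfg.validate()


def test_count_mode_keeps_rates_consistent_with_list_size():
    cfg = SimConfig(n_treated=2, n_donors=8, n_months=24, join_months=(10, 14),
                    count_mode=True, seed=3)
    panel, _ = generate_panel(cfg)
    events = panel["adm_rate"] * panel["list_size"] / 100.0
    np.testing.assert_allclose(events, np.round(events), atol=1e-9)
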