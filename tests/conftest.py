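"""Shared fixtures: hand-built panels and scaled-down simulation configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scmeval.panel import COVARIATE_COLUMNS, OUTCOME_COLUMNS, PANEL_COLUMNS
from scmeval.simulate import SimConfig

_COVARIATE_DEFAULTS = {
    "gp_count": 4.0,
    "nurse_count": 2.0,
    "bme_pct": 20.0,
    "female_0_19_pct": 11.0,
    "female_20_64_pct": 29.0,
    "female_65_plus_pct": 10.0,
    "male_0_19_pct": 12.0,
    "male_20_64_pct": 30.0,
    "male_65_plus_pct": 8.0,
    "imd": 25.0,
    "urban_pct": 90.0,
    "ltc_prev": 20.0,
    "diabetes_prev": 7.0,
}


def build_panel(series: dict[str, dict], n_months: int) -> pd.DataFrame:
    """Construct a schema-complete panel from per-practice column overrides.

    ``series[pid]`` maps column name -> scalar or length-``n_months`` array;
    any column not given falls back to a constant default.
    """
    months = np.arange(1, n_months + 1)
    frames = []
    for pid, overrides in series.items():
        row = {"practice_id": pid, "month_index": months}
        defaults = {"list_size": 5000.0, "em_los": 5.0}
        defaults.update({c: 1.0 for c in OUTCOME_COLUMNS})
        defaults.update(_COVARIATE_DEFAULTS)
        defaults.update(overrides)
        for col in PANEL_COLUMNS:
            if col in ("practice_id", "month_index"):
                continue
            value = defaults[col]
            row[col] = np.broadcast_to(np.asarray(value, dtype=float), months.shape).copy()
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)[list(PANEL_COLUMNS)]


@pytest.fixture
def make_panel():
    return build_panel


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study: 3 treated, 16 donors, 30 months."""
    return SimConfig(
        n_treated=3,
        n_donors=16,
        n_months=30,
        join_months=(12, 16, 20),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    from scmeval.simulate import generate_panel

    return generate_panel(small_config)


def tiny_pipeline_config(seed: int = 5) -> dict:
    """Pipeline config small enough for sub-10-second end-to-end runs."""
    from scmeval.pipeline import default_config

    cfg = default_config()
    cfg["seed"] = seed
    cfg["data"]["simulate"] = {
        "n_treated": 3,
        "n_donors": 16,
        "n_months": 30,
        "join_months": [12, 16, 20],
    }
    cfg["scm"]["multistarts"] = 0
    cfg["scm"]["nm_maxiter"] = 0
    cfg["donors"]["min_pool"] = 11
    cfg["inference"]["min_placebos"] = 8
    return cfg
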