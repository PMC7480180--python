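"""Panel storage: schema, validation, CSV/YAML round-trips, donor pools.

A *monthly panel* is a long-format :class:`pandas.DataFrame` with one row per
(practice, month): three unplanned-care outcome rates per 100 registered
patients (ED attendances, unplanned admissions, unplanned readmissions),
emergency length of stay, list size and practice covariates.  The
*intervention schedule* records when each treated practice joined the
vertical-integration programme (and, optionally, when it left); it defines
the pre/post windows used everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DonorPoolError, PanelSchemaError

#: Three outcome-rate columns, in canonical order (ED, admissions, readmissions).
OUTCOME_COLUMNS = ("ed_rate", "adm_rate", "readm_rate")

#: Practice covariates emitted by the simulator and accepted as predictors.
COVARIATE_COLUMNS = (
    "gp_count",
    "nurse_count",
    "bme_pct",
    "female_0_19_pct",
    "female_20_64_pct",
    "female_65_plus_pct",
    "male_0_19_pct",
    "male_20_64_pct",
    "male_65_plus_pct",
    "imd",
    "urban_pct",
    "ltc_prev",
    "diabetes_prev",
)

#: Fixed CSV header for a monthly panel.
PANEL_COLUMNS = (
    "practice_id",
    "month_index",
    "list_size",
    "ed_rate",
    "adm_rate",
    "readm_rate",
    "em_los",
) + COVARIATE_COLUMNS

_RATE_LIKE = OUTCOME_COLUMNS + ("em_los",)


@dataclass(frozen=True)
class InterventionSchedule:
    """Per-practice join month (1-based) and optional exit month.

    A practice that exits is analysed up to the month before its exit; the
    invariant ``join < exit`` guarantees a non-empty post window.
    """

    entries: Mapping[str, tuple[int, Optional[int]]]

    def __post_init__(self):
        for pid, (join, exit_month) in self.entries.items():
            if exit_month is not None and not join < exit_month:
                raise PanelSchemaError(
                    f"practice {pid!r}: join month {join} must precede exit month {exit_month}"
                )

    @property
    def treated_ids(self) -> list[str]:
        return sorted(self.entries)

    def join_month(self, practice_id: str) -> int:
        return self.entries[practice_id][0]

    def exit_month(self, practice_id: str) -> Optional[int]:
        return self.entries[practice_id][1]

    def post_window(self, practice_id: str, n_months: int) -> tuple[int, int]:
        """Post-intervention window: join month through the last analysed month."""
        join, exit_month = self.entries[practice_id]
        end = n_months if exit_month is None else exit_month - 1
        return join, end

    def to_yaml(self, path) -> None:
        payload = {
            pid: (
                {"join_month": int(j)}
                if e is None
                else {"join_month": int(j), "exit_month": int(e)}
            )
            for pid, (j, e) in self.entries.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "InterventionSchedule":
        payload = yaml.safe_load(Path(path).read_text())
        entries = {
            str(pid): (int(rec["join_month"]), rec.get("exit_month"))
            for pid, rec in payload.items()
        }
        return cls(entries)


@dataclass
class DonorPool:
    """Candidate control practices for one treated practice.

    ``constraint_log`` records, for every non-self practice in the panel,
    whether it was included or why it was excluded ("treated", "list_size",
    "group").
    """

    treated_id: str
    donor_ids: list[str]
    constraint_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.treated_id in self.donor_ids:
            raise DonorPoolError(f"treated practice {self.treated_id!r} in its own donor pool")
        if not self.donor_ids:
            raise DonorPoolError(
                f"empty donor pool for {self.treated_id!r}; "
                "consider increasing the list-size tolerance"
            )


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a monthly panel against the declared schema.

    Checks header, numeric dtypes, non-negative rates, unique
    (practice, month) keys and rectangular month coverage.  Returns the
    frame sorted by (practice_id, month_index).
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelSchemaError(f"panel missing required columns: {missing}")
    panel = panel.loc[:, list(PANEL_COLUMNS)].copy()

    for col in PANEL_COLUMNS:
        if col == "practice_id":
            continue
        values = pd.to_numeric(panel[col], errors="coerce")
        bad = values.isna() & panel[col].notna() | panel[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelSchemaError("non-numeric or missing value", row=row, column=col)
        panel[col] = values

    for col in _RATE_LIKE:
        neg = panel[col] < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise PanelSchemaError(f"negative value in {col!r}", row=row, column=col)

    dup = panel.duplicated(subset=["practice_id", "month_index"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise PanelSchemaError("duplicate (practice_id, month_index) key", row=row,
                               column="month_index")

    months = np.sort(panel["month_index"].unique())
    expected = np.arange(months.min(), months.max() + 1)
    if not np.array_equal(months, expected):
        raise PanelSchemaError(
            f"panel months are not contiguous: have {months.tolist()}", column="month_index"
        )
    counts = panel.groupby("practice_id")["month_index"].agg(["size", "nunique"])
    ragged = counts[(counts["size"] != len(expected)) | (counts["nunique"] != len(expected))]
    if len(ragged):
        pid = ragged.index[0]
        have = set(panel.loc[panel["practice_id"] == pid, "month_index"])
        lacking = sorted(set(expected.tolist()) - have)
        raise PanelSchemaError(
            f"ragged month coverage for practice {pid!r}: missing months {lacking}",
            column="month_index",
        )

    return panel.sort_values(["practice_id", "month_index"], kind="mergesort").reset_index(drop=True)


def load_panel(path) -> pd.DataFrame:
    """Read and validate a monthly panel CSV."""
    try:
        raw = pd.read_csv(path, dtype={"practice_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelSchemaError(f"cannot read panel CSV {path}: {exc}") from exc
    return validate_panel(raw)


def save_panel(panel: pd.DataFrame, path) -> None:
    """Write a monthly panel CSV with the fixed header order."""
    validate_panel(panel).to_csv(path, index=False)


def panel_months(panel: pd.DataFrame) -> tuple[int, int]:
    m = panel["month_index"]
    return int(m.min()), int(m.max())


def outcome_wide(panel: pd.DataFrame, column: str) -> pd.DataFrame:
    """Pivot one panel column to a months x practices matrix."""
    return panel.pivot(index="month_index", columns="practice_id", values=column)


def build_donor_pool(
    panel: pd.DataFrame,
    schedule: InterventionSchedule,
    treated_id: str,
    tolerance: float = 0.20,
    group_col: Optional[str] = None,
) -> DonorPool:
    """Select donors with a similar list size to the treated practice.

    Comparison is made at the month before the treated practice joins (the
    month in which baseline characteristics are defined).  A candidate with
    list size in the closed band ``[(1 - tolerance) L, (1 + tolerance) L]``
    of the treated practice's list size ``L`` is included; all practices on
    the intervention schedule are excluded from every pool.  When
    ``group_col`` names a categorical panel column, donors must additionally
    share the treated practice's value (a stand-in for the study's
    geographic restriction to nearby commissioning groups).
    """
    if treated_id not in schedule.entries:
        raise DonorPoolError(f"{treated_id!r} is not on the intervention schedule")
    if not 0 < tolerance < 1:
        raise DonorPoolError(f"tolerance must be in (0, 1), got {tolerance}")

    join = schedule.join_month(treated_id)
    ref_month = max(join - 1, panel_months(panel)[0])
    at_ref = panel[panel["month_index"] == ref_month].set_index("practice_id")
    if treated_id not in at_ref.index:
        raise DonorPoolError(f"practice {treated_id!r} not present in panel")
    treated_size = float(at_ref.loc[treated_id, "list_size"])
    lo, hi = (1 - tolerance) * treated_size, (1 + tolerance) * treated_size
    treated_group = at_ref.loc[treated_id, group_col] if group_col else None

    log: dict[str, str] = {}
    donors: list[str] = []
    for pid in sorted(at_ref.index):
        if pid == treated_id:
            continue
        if pid in schedule.entries:
            log[pid] = "treated"
            continue
        if group_col is not None and at_ref.loc[pid, group_col] != treated_group:
            log[pid] = "group"
            continue
        size = float(at_ref.loc[pid, "list_size"])
        if not lo <= size <= hi:
            log[pid] = "list_size"
            continue
        log[pid] = "included"
        donors.append(pid)

    if not donors:
        raise DonorPoolError(
            f"no eligible donors for {treated_id!r} at tolerance {tolerance:.2f}; "
            "increase the tolerance"
        )
    return DonorPool(treated_id=treated_id, donor_ids=donors, constraint_log=log)
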