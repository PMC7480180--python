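"""Multivariate synthetic-control fitting.

A synthetic control for a treated practice is a convex combination of donor
practices chosen so that its pre-intervention covariate means and monthly
outcome paths reproduce the treated practice's.  The fit is the standard
nested formulation:

* inner problem — given diagonal predictor-importance weights ``V``, donor
  weights ``W`` minimise ``(X1 - X0 W)' diag(V) (X1 - X0 W)`` over the
  probability simplex;
* outer problem — ``V`` is chosen to minimise the pre-period mean squared
  prediction error (MSPE) of the resulting synthetic outcome paths.

``V`` is searched at the level of predictor groups (one weight per
covariate, one per outcome series, spread uniformly over that series'
monthly rows); the search runs Nelder--Mead from a fixed set of starts:
equal weights, an outcome-only start whose inner solution provably attains
the global minimum of the outer MSPE over the simplex, and seeded random
starts.  The inner problem is solved exactly as a penalised non-negative
least-squares system.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitError
from .panel import COVARIATE_COLUMNS, OUTCOME_COLUMNS, DonorPool, outcome_wide

DEFAULT_COVARIATES = ("list_size", "em_los") + COVARIATE_COLUMNS


@dataclass(frozen=True)
class PredictorSpec:
    """Which panel columns enter the matching problem.

    Covariates are matched as pre-period means; each outcome is matched as
    its full monthly pre-period path.  With ``standardize`` each predictor
    row is divided by its donor-pool standard deviation so that no predictor
    dominates through scale alone.
    """

    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    outcome_names: tuple[str, ...] = OUTCOME_COLUMNS
    standardize: bool = True

    def __post_init__(self):
        if not self.outcome_names:
            raise FitError("PredictorSpec needs at least one outcome series")


@dataclass(frozen=True)
class FitSettings:
    """Optimiser configuration for the outer V-search.

    ``n_multistarts`` seeded random Dirichlet starts are polished with
    Nelder--Mead (``nm_maxiter`` iterations each) in addition to the equal
    and outcome-only starts; ``n_multistarts=0, nm_maxiter=0`` evaluates the
    fixed starts only, which already attains the optimal outer MSPE and is
    the fast preset used for large placebo studies.
    """

    n_multistarts: int = 5
    nm_maxiter: int = 150
    seed: int = 0
    mspe_cap: Optional[float] = None


FAST_SETTINGS = FitSettings(n_multistarts=0, nm_maxiter=0)


@dataclass
class ScmMatrices:
    """Assembled matching problem for one treated practice."""

    treated_id: str
    donor_ids: list[str]
    X1: np.ndarray  # (n_predictors,)
    X0: np.ndarray  # (n_predictors, n_donors)
    Z1: np.ndarray  # (n_outcomes * n_pre,) raw outcome paths
    Z0: np.ndarray  # (n_outcomes * n_pre, n_donors)
    row_names: list[str]
    row_groups: np.ndarray  # group index per X row
    group_names: list[str]
    row_scales: np.ndarray  # donor SD used to standardise each X row (1 if raw)
    outcome_names: tuple[str, ...]
    n_pre: int


@dataclass
class ScmFit:
    """Result of one synthetic-control fit.

    ``W`` (donor weights) and ``V`` (per-row predictor weights) both lie on
    the probability simplex; ``pre_mspe`` is the raw-scale mean squared
    pre-period error per outcome and ``objective`` their overall mean.
    """

    treated_id: str
    donor_ids: list[str]
    W: np.ndarray
    V: np.ndarray
    v_rows: list[str]
    pre_mspe: dict[str, float]
    objective: float
    converged: bool
    outcome_names: tuple[str, ...] = OUTCOME_COLUMNS

    def weights(self, threshold: float = 0.0) -> dict[str, float]:
        return {
            pid: float(w)
            for pid, w in zip(self.donor_ids, self.W)
            if w > threshold
        }


def make_wide_cache(panel: pd.DataFrame, spec: PredictorSpec) -> dict[str, pd.DataFrame]:
    """Pivot every predictor/outcome column once (months x practices).

    Fitting many units against the same panel (placebo tests, replicate
    studies) is dominated by pivoting; passing this cache to
    :func:`assemble_matrices` turns assembly into array slicing.
    """
    columns = set(spec.covariate_names) | set(spec.outcome_names)
    missing = sorted(c for c in columns if c not in panel.columns)
    if missing:
        raise FitError(f"predictor column(s) {missing} not in panel")
    return {c: outcome_wide(panel, c) for c in columns}


def assemble_matrices(
    panel: pd.DataFrame,
    pool: DonorPool,
    spec: PredictorSpec,
    pre_window: tuple[int, int],
    wides: Optional[dict[str, pd.DataFrame]] = None,
) -> ScmMatrices:
    """Build X/Z blocks for the nested problem.

    ``pre_window`` is the inclusive (first, last) month of the
    pre-intervention period; it must end the month before the treated
    practice joins.  X stacks covariate pre-means and outcome pre-paths;
    Z holds the raw outcome pre-paths used by the outer objective.
    Standardised rows with zero donor-pool SD are dropped with a warning;
    an outcome whose entire path has zero donor variance is an error.
    """
    lo, hi = pre_window
    if hi < lo:
        raise FitError(f"empty pre-window {pre_window}")
    if wides is None:
        wides = make_wide_cache(panel, spec)
    cols = [pool.treated_id] + list(pool.donor_ids)

    def pre_block(name: str) -> np.ndarray:
        if name not in wides:
            raise FitError(f"predictor column {name!r} not in panel")
        block = wides[name].loc[lo:hi, cols]
        if block.empty:
            raise FitError(f"pre-window {pre_window} outside panel months")
        return block.to_numpy()

    rows, names, groups, group_names = [], [], [], []
    for name in spec.covariate_names:
        wide = pre_block(name)
        group_names.append(name)
        groups.append(len(group_names) - 1)
        names.append(name)
        rows.append(wide.mean(axis=0))

    z_rows = []
    n_pre = hi - lo + 1
    for outcome in spec.outcome_names:
        wide = pre_block(outcome)  # (n_pre, 1 + n_donors)
        if np.allclose(wide[:, 1:].std(axis=1), 0.0):
            raise FitError(f"outcome {outcome!r} has zero variance across donors")
        group_names.append(outcome)
        g = len(group_names) - 1
        for t in range(n_pre):
            names.append(f"{outcome}[m{lo + t}]")
            groups.append(g)
            rows.append(wide[t])
        z_rows.append(wide)

    X = np.asarray(rows)  # (n_rows, 1 + n_donors)
    groups_arr = np.asarray(groups)
    scales = np.ones(len(X))
    if spec.standardize:
        sd = X[:, 1:].std(axis=1, ddof=1) if X.shape[1] > 2 else X[:, 1:].std(axis=1)
        keep = sd > 0
        if not keep.all():
            dropped = [names[i] for i in np.flatnonzero(~keep)]
            warnings.warn(
                f"dropping {len(dropped)} zero-variance predictor row(s): {dropped[:5]}",
                stacklevel=2,
            )
        X = X[keep] / sd[keep][:, None]
        scales = sd[keep]
        names = [n for n, k in zip(names, keep) if k]
        groups_arr = groups_arr[keep]

    Z = np.vstack(z_rows).reshape(-1, len(cols))
    return ScmMatrices(
        treated_id=pool.treated_id,
        donor_ids=list(pool.donor_ids),
        X1=X[:, 0],
        X0=X[:, 1:],
        Z1=Z[:, 0],
        Z0=Z[:, 1:],
        row_names=names,
        row_groups=groups_arr,
        group_names=group_names,
        row_scales=scales,
        outcome_names=tuple(spec.outcome_names),
        n_pre=n_pre,
    )


def solve_inner_weights(X1: np.ndarray, X0: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Donor weights minimising the V-weighted match over the simplex.

    The simplex-constrained weighted least-squares problem is solved as an
    exact non-negative least-squares system augmented with a heavily
    penalised sum-to-one row, followed by renormalisation (which preserves
    feasibility exactly and perturbs the objective negligibly).
    """
    X1 = np.asarray(X1, dtype=float).ravel()
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    V = np.asarray(V, dtype=float).ravel()
    if X0.shape[0] != X1.size or V.size != X1.size:
        raise FitError(
            f"shape mismatch: X1 {X1.shape}, X0 {X0.shape}, V {V.shape}"
        )
    if np.any(V < 0):
        raise FitError("V must be non-negative")
    n_donors = X0.shape[1]
    if n_donors == 1:
        return np.ones(1)

    sv = np.sqrt(V)
    A = X0 * sv[:, None]
    b = X1 * sv
    scale = max(1.0, float(np.abs(A).max()))
    mu = 1e4 * scale
    A_aug = np.vstack([A, np.full((1, n_donors), mu)])
    b_aug = np.append(b, mu)
    try:
        W, _ = optimize.nnls(A_aug, b_aug)
    except Exception as exc:  # pragma: no cover - nnls rarely fails
        raise FitError(f"inner NNLS failed: {exc}") from exc
    total = W.sum()
    if total <= 0:  # pragma: no cover - mu forces a positive sum
        raise FitError("inner solver returned a degenerate all-zero weight vector")
    return W / total


def _expand_group_v(v_groups: np.ndarray, row_groups: np.ndarray) -> np.ndarray:
    """Spread each group weight uniformly over that group's rows."""
    counts = np.bincount(row_groups, minlength=v_groups.size).astype(float)
    counts[counts == 0] = 1.0
    V = v_groups[row_groups] / counts[row_groups]
    total = V.sum()
    return V / total if total > 0 else np.full_like(V, 1.0 / V.size)


def _outer_mspe(W: np.ndarray, mats: ScmMatrices) -> float:
    resid = mats.Z1 - mats.Z0 @ W
    return float(np.mean(resid**2))


def _outcome_only_v_groups(mats: ScmMatrices) -> np.ndarray:
    """Group weights whose inner solution minimises the outer MSPE.

    Putting weight proportional to (row scale)^2 on the outcome rows and
    zero on covariates makes the inner weighted objective equal the raw
    outer squared error, so W(V) is the global simplex minimiser of the
    outer MSPE.  Returned at group level: each outcome group gets the sum
    of its rows' squared scales.
    """
    n_groups = len(mats.group_names)
    v = np.zeros(n_groups)
    is_outcome = {
        g: name in mats.outcome_names for g, name in enumerate(mats.group_names)
    }
    for g in range(n_groups):
        if is_outcome[g]:
            rows = mats.row_groups == g
            v[g] = float(np.sum(mats.row_scales[rows] ** 2))
    total = v.sum()
    if total <= 0:  # all outcome rows dropped — cannot happen past assemble
        raise FitError("no outcome rows available for the outer objective")
    return v / total


def _outcome_only_row_v(mats: ScmMatrices) -> np.ndarray:
    V = np.zeros(len(mats.X1))
    for g, name in enumerate(mats.group_names):
        if name in mats.outcome_names:
            rows = mats.row_groups == g
            V[rows] = mats.row_scales[rows] ** 2
    return V / V.sum()


def fit_from_matrices(mats: ScmMatrices, settings: FitSettings = FitSettings()) -> ScmFit:
    """Run the nested V/W optimisation on pre-assembled matrices."""
    n_groups = len(mats.group_names)

    def objective_rows(V_rows: np.ndarray) -> tuple[float, np.ndarray]:
        W = solve_inner_weights(mats.X1, mats.X0, V_rows)
        return _outer_mspe(W, mats), W

    def objective_logits(z: np.ndarray) -> float:
        z = z - z.max()
        v_groups = np.exp(z)
        v_groups /= v_groups.sum()
        V_rows = _expand_group_v(v_groups, mats.row_groups)
        return objective_rows(V_rows)[0]

    # Fixed starts: equal row weights, and the outcome-only start whose inner
    # solution attains the global outer-MSPE minimum over the simplex.
    candidates: list[np.ndarray] = [np.full(len(mats.X1), 1.0 / len(mats.X1))]
    oracle_rows = _outcome_only_row_v(mats)
    candidates.append(oracle_rows)

    rng = np.random.default_rng(settings.seed)
    group_starts = [np.full(n_groups, 1.0 / n_groups), _outcome_only_v_groups(mats)]
    group_starts += [rng.dirichlet(np.ones(n_groups)) for _ in range(settings.n_multistarts)]

    converged = True
    if settings.nm_maxiter > 0:
        for v0 in group_starts:
            z0 = np.log(np.maximum(v0, 1e-12))
            res = optimize.minimize(
                objective_logits,
                z0,
                method="Nelder-Mead",
                options={"maxiter": settings.nm_maxiter, "xatol": 1e-6, "fatol": 1e-12},
            )
            z = res.x - res.x.max()
            v_groups = np.exp(z)
            v_groups /= v_groups.sum()
            candidates.append(_expand_group_v(v_groups, mats.row_groups))

    best: Optional[tuple[float, np.ndarray, np.ndarray]] = None
    for V_rows in candidates:
        obj, W = objective_rows(V_rows)
        if (
            best is None
            or obj < best[0] - 1e-12
            or (abs(obj - best[0]) <= 1e-12 and tuple(W) < tuple(best[1]))
        ):
            best = (obj, W, V_rows)

    assert best is not None
    obj, W, V_rows = best
    n_pre = mats.n_pre
    pre_mspe = {}
    for k, outcome in enumerate(mats.outcome_names):
        block = slice(k * n_pre, (k + 1) * n_pre)
        resid = mats.Z1[block] - mats.Z0[block] @ W
        pre_mspe[outcome] = float(np.mean(resid**2))

    if settings.mspe_cap is not None and obj > settings.mspe_cap:
        warnings.warn(
            f"pre-period MSPE {obj:.4g} exceeds cap {settings.mspe_cap:.4g} "
            f"for {mats.treated_id}",
            stacklevel=2,
        )
    return ScmFit(
        treated_id=mats.treated_id,
        donor_ids=list(mats.donor_ids),
        W=W,
        V=V_rows,
        v_rows=list(mats.row_names),
        pre_mspe=pre_mspe,
        objective=obj,
        converged=converged,
        outcome_names=mats.outcome_names,
    )


def fit_synthetic_control(
    panel: pd.DataFrame,
    pool: DonorPool,
    spec: PredictorSpec = PredictorSpec(),
    pre_window: tuple[int, int] = (1, 1),
    settings: FitSettings = FitSettings(),
) -> ScmFit:
    """Assemble matrices and fit one synthetic control (deterministic)."""
    mats = assemble_matrices(panel, pool, spec, pre_window)
    return fit_from_matrices(mats, settings)


def predict_outcomes(
    fit: ScmFit,
    panel: pd.DataFrame,
    months: tuple[int, int],
) -> pd.DataFrame:
    """Synthetic-control outcome paths over an inclusive month range.

    Each column is the W-weighted combination of the donor practices'
    observed paths, so every value lies within the pointwise donor range.
    """
    lo, hi = months
    sub = panel[(panel["month_index"] >= lo) & (panel["month_index"] <= hi)]
    if sub["month_index"].nunique() != hi - lo + 1:
        raise FitError(f"months {months} not fully covered by panel")
    out = {}
    for outcome in fit.outcome_names:
        wide = outcome_wide(sub, outcome)[fit.donor_ids].to_numpy()
        out[outcome] = wide @ fit.W
    return pd.DataFrame(out, index=pd.RangeIndex(lo, hi + 1, name="month_index"))


def grid_simplex(n: int, step: float):
    """Yield all simplex points with coordinates on a grid of the given step.

    Brute-force oracle used for testing small problems; the number of points
    grows combinatorially so keep ``n`` and ``1/step`` small.
    """
    k = int(round(1.0 / step))
    for comp in itertools.combinations_with_replacement(range(n), k):
        w = np.zeros(n)
        for idx in comp:
            w[idx] += 1
        yield w / k
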