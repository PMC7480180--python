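"""Inverse-variance pooling of per-practice effects with heterogeneity.

The programme-level effect per outcome combines the per-practice estimates
with inverse-variance weights.  Heterogeneity between practices is assessed
with Cochran's Q and Higgins & Thompson's I^2 (with a test-based confidence
interval on the log of H = sqrt(Q/df)); between-practice variance tau^2
uses the DerSimonian--Laird moment estimator.  Following the study design,
the fixed-effect model is reported when the Q test is not significant at
alpha = 0.05 and the random-effects model otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ScmevalError


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    q_p: float
    i2: float
    i2_ci95: tuple[float, float]
    tau2: float


@dataclass
class PooledEffect:
    """Inverse-variance combined effect for one outcome across practices."""

    outcome: str
    delta_pooled: float
    se_pooled: float
    ci95: tuple[float, float]
    p: float
    Q: float
    df: int
    q_p: float
    i2: float
    i2_ci95: tuple[float, float]
    tau2: float
    model: str  # "fixed" or "random"
    k: int


def _extract(estimates) -> tuple[np.ndarray, np.ndarray, str]:
    deltas, ses, outcome = [], [], ""
    for est in estimates:
        if hasattr(est, "delta"):
            deltas.append(float(est.delta))
            ses.append(float(est.se))
            outcome = getattr(est, "outcome", outcome) or outcome
        else:
            d, s = est
            deltas.append(float(d))
            ses.append(float(s))
    deltas_arr, ses_arr = np.asarray(deltas), np.asarray(ses)
    if np.any(ses_arr <= 0):
        raise ScmevalError("all standard errors must be positive for pooling")
    return deltas_arr, ses_arr, outcome


def _finalise(outcome, delta, se, het, model, k) -> PooledEffect:
    p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return PooledEffect(
        outcome=outcome,
        delta_pooled=float(delta),
        se_pooled=float(se),
        ci95=(float(delta - 1.96 * se), float(delta + 1.96 * se)),
        p=p,
        Q=het.Q,
        df=het.df,
        q_p=het.q_p,
        i2=het.i2,
        i2_ci95=het.i2_ci95,
        tau2=het.tau2,
        model=model,
        k=k,
    )


def heterogeneity(estimates: Iterable) -> HeterogeneityResult:
    """Cochran's Q, I^2 with test-based 95% CI, and DerSimonian--Laird tau^2.

    ``Q = sum w_i (delta_i - delta_fixed)^2`` with ``w_i = 1/se_i^2``;
    ``I^2 = max(0, (Q - df)/Q) * 100``;
    ``tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))``.
    The I^2 interval transforms a normal interval for ln H back to the I^2
    scale, with H floored at 1.
    """
    deltas, ses, _ = _extract(estimates)
    k = deltas.size
    if k < 2:
        raise ScmevalError("heterogeneity needs at least two estimates")
    w = 1.0 / ses**2
    fixed = float(np.sum(w * deltas) / np.sum(w))
    Q = float(np.sum(w * (deltas - fixed) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(Q, df))
    i2 = 0.0 if Q <= 0 else max(0.0, (Q - df) / Q) * 100.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0

    # Test-based CI for ln H (H = sqrt(Q/df)), Higgins & Thompson style.
    if Q > df and Q > 0:
        se_ln_h = 0.5 * (np.log(Q) - np.log(df)) / (np.sqrt(2 * Q) - np.sqrt(2 * df - 1))
    elif df > 1:
        se_ln_h = np.sqrt(1.0 / (2.0 * (df - 1)) * (1.0 - 1.0 / (3.0 * (df - 1) ** 2)))
    else:
        se_ln_h = 0.0
    ln_h = 0.5 * np.log(max(Q, 1e-300) / df) if Q > 0 else 0.0
    h_lo = max(1.0, np.exp(ln_h - 1.96 * se_ln_h))
    h_hi = max(1.0, np.exp(ln_h + 1.96 * se_ln_h))
    to_i2 = lambda h: 0.0 if h <= 1 else (h**2 - 1.0) / h**2 * 100.0
    i2_ci = (to_i2(h_lo), to_i2(h_hi))
    return HeterogeneityResult(Q=Q, df=df, q_p=q_p, i2=float(i2), i2_ci95=i2_ci, tau2=float(tau2))


def pool_fixed(estimates: Sequence, allow_single: bool = False) -> PooledEffect:
    """Fixed-effect inverse-variance pooling.

    ``delta = sum(w_i d_i) / sum(w_i)`` and ``se = 1/sqrt(sum w_i)`` with
    ``w_i = 1/se_i^2``.  With ``allow_single`` a single estimate is passed
    through unchanged (Q = 0, df = 0).
    """
    deltas, ses, outcome = _extract(estimates)
    k = deltas.size
    if k < 2:
        if k == 1 and allow_single:
            het = HeterogeneityResult(0.0, 0, 1.0, 0.0, (0.0, 0.0), 0.0)
            return _finalise(outcome, deltas[0], ses[0], het, "fixed", 1)
        raise ScmevalError("pooling needs at least two estimates")
    w = 1.0 / ses**2
    delta = np.sum(w * deltas) / np.sum(w)
    se = 1.0 / np.sqrt(np.sum(w))
    het = heterogeneity(list(zip(deltas, ses)))
    return _finalise(outcome, delta, se, het, "fixed", k)


def pool_random(estimates: Sequence) -> PooledEffect:
    """Random-effects (DerSimonian--Laird) inverse-variance pooling."""
    deltas, ses, outcome = _extract(estimates)
    if deltas.size < 2:
        raise ScmevalError("pooling needs at least two estimates")
    het = heterogeneity(list(zip(deltas, ses)))
    w = 1.0 / (ses**2 + het.tau2)
    delta = np.sum(w * deltas) / np.sum(w)
    se = 1.0 / np.sqrt(np.sum(w))
    return _finalise(outcome, delta, se, het, "random", deltas.size)


def pool_auto(estimates: Sequence, alpha: float = 0.05) -> PooledEffect:
    """Fixed-effect pooling unless the Q test is significant at ``alpha``.

    The study decision rule: heterogeneity not significant -> fixed effect;
    otherwise random effects.  The resulting ``model`` field records the
    choice.
    """
    het = heterogeneity(estimates)
    if het.q_p >= alpha:
        return pool_fixed(estimates)
    return pool_random(estimates)
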