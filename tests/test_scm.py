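"""Synthetic-control core: matrix assembly, inner QP, nested fit."""

import numpy as np
import pytest

from scmeval.errors import FitError
from scmeval.panel import DonorPool, InterventionSchedule, build_donor_pool
from scmeval.scm import (
    FAST_SETTINGS,
    FitSettings,
    PredictorSpec,
    ScmFit,
    assemble_matrices,
    fit_synthetic_control,
    grid_simplex,
    predict_outcomes,
    solve_inner_weights,
)

from conftest import build_panel

RNG = np.random.default_rng(1234)


def weighted_objective(X1, X0, V, W):
    r = X1 - X0 @ W
    return float(r @ (V * r))


def outer_mspe(Z1, Z0, W):
    r = Z1 - Z0 @ W
    return float(np.mean(r**2))


# ---------------------------------------------------------------- assembly


def simple_pool(donors):
    return DonorPool(treated_id="T", donor_ids=list(donors))


def test_matrix_dimensions_two_covariates_three_outcomes():
    series = {pid: {"ed_rate": RNG.uniform(1, 3, 20),
                    "adm_rate": RNG.uniform(0.5, 1.5, 20),
                    "readm_rate": RNG.uniform(0.05, 0.2, 20)}
              for pid in ["T", "A", "B", "C"]}
    panel = build_panel(series, n_months=20)
    spec = PredictorSpec(covariate_names=("list_size", "imd"), standardize=False)
    mats = assemble_matrices(panel, simple_pool("ABC"), spec, pre_window=(1, 12))
    assert mats.X1.shape == (2 + 3 * 12,)
    assert mats.X0.shape == (2 + 3 * 12, 3)
    assert mats.Z1.shape == (3 * 12,)
    assert mats.Z0.shape == (3 * 12, 3)


def test_clone_donor_column_equals_treated_vector():
    path = {"ed_rate": RNG.uniform(1, 3, 16), "adm_rate": RNG.uniform(0.5, 1.5, 16),
            "readm_rate": RNG.uniform(0.05, 0.2, 16), "imd": 33.0}
    other = {"ed_rate": RNG.uniform(1, 3, 16), "adm_rate": RNG.uniform(0.5, 1.5, 16),
             "readm_rate": RNG.uniform(0.05, 0.2, 16)}
    panel = build_panel({"T": dict(path), "CLONE": dict(path), "B": other}, n_months=16)
    spec = PredictorSpec(covariate_names=("imd",), standardize=True)
    mats = assemble_matrices(panel, simple_pool(["CLONE", "B"]), spec, (1, 10))
    np.testing.assert_allclose(mats.X0[:, 0], mats.X1, atol=1e-12)


def test_zero_variance_predictor_row_is_dropped_with_warning():
    series = {pid: {"ed_rate": RNG.uniform(1, 3, 16),
                    "adm_rate": RNG.uniform(0.5, 1.5, 16),
                    "readm_rate": RNG.uniform(0.05, 0.2, 16),
                    "imd": 30.0}  # constant across donors
              for pid in ["T", "A", "B", "C"]}
    panel = build_panel(series, n_months=16)
    spec = PredictorSpec(covariate_names=("imd",), standardize=True)
    with pytest.warns(UserWarning, match="zero-variance"):
        mats = assemble_matrices(panel, simple_pool("ABC"), spec, (1, 10))
    assert "imd" not in mats.row_names


def test_constant_outcome_across_donors_is_an_error():
    series = {pid: {"ed_rate": RNG.uniform(1, 3, 16)} for pid in ["T", "A", "B"]}
    panel = build_panel(series, n_months=16)  # adm/readm constant everywhere
    spec = PredictorSpec(covariate_names=(), standardize=False)
    with pytest.raises(FitError, match="zero variance"):
        assemble_matrices(panel, simple_pool("AB"), spec, (1, 10))


# ------------------------------------------------------------ inner solver


def test_single_donor_weight_is_forced_to_one():
    W = solve_inner_weights(np.array([1.0, 2.0]), np.array([[0.5], [1.5]]), np.array([0.5, 0.5]))
    np.testing.assert_allclose(W, [1.0])


def test_midpoint_target_splits_weight_evenly():
    a = RNG.normal(size=8)
    b = RNG.normal(size=8)
    X0 = np.column_stack([a, b])
    X1 = 0.5 * (a + b)
    V = np.full(8, 1.0 / 8)
    W = solve_inner_weights(X1, X0, V)
    np.testing.assert_allclose(W, [0.5, 0.5], atol=1e-3)


@pytest.mark.parametrize("trial", range(5))
def test_inner_solution_matches_brute_force_grid(trial):
    rng = np.random.default_rng(100 + trial)
    X0 = rng.normal(size=(6, 3))
    X1 = rng.normal(size=6)
    V = rng.dirichlet(np.ones(6))
    W = solve_inner_weights(X1, X0, V)
    assert np.all(W >= -1e-12) and abs(W.sum() - 1) < 1e-6
    obj = weighted_objective(X1, X0, V, W)
    grid_best = min(weighted_objective(X1, X0, V, w) for w in grid_simplex(3, 0.01))
    assert obj <= grid_best + 1e-3


# -------------------------------------------------------------- nested fit


def random_outcome_series(rng, n_months, means=(2.5, 0.9, 0.12)):
    return {
        "ed_rate": np.abs(means[0] + rng.normal(0, 0.3, n_months)),
        "adm_rate": np.abs(means[1] + rng.normal(0, 0.12, n_months)),
        "readm_rate": np.abs(means[2] + rng.normal(0, 0.04, n_months)),
    }


def test_perfect_match_puts_all_weight_on_the_clone():
    rng = np.random.default_rng(7)
    target = random_outcome_series(rng, 20)
    series = {"T": dict(target), "CLONE": dict(target)}
    for pid in ["A", "B", "C"]:
        series[pid] = random_outcome_series(rng, 20)
    panel = build_panel(series, n_months=20)
    fit = fit_synthetic_control(
        panel, simple_pool(["CLONE", "A", "B", "C"]),
        PredictorSpec(covariate_names=(), standardize=False), (1, 14), FitSettings()
    )
    assert fit.W[0] >= 1 - 1e-4
    assert fit.objective <= 1e-10
    for v in fit.pre_mspe.values():
        assert v <= 1e-10


def test_average_of_two_donors_recovers_half_half():
    rng = np.random.default_rng(8)
    a = random_outcome_series(rng, 24)
    b = random_outcome_series(rng, 24)
    treated = {k: 0.5 * (a[k] + b[k]) for k in a}
    noise = random_outcome_series(rng, 24)
    panel = build_panel({"T": treated, "A": a, "B": b, "C": noise}, n_months=24)
    fit = fit_synthetic_control(
        panel, simple_pool("ABC"),
        PredictorSpec(covariate_names=(), standardize=False), (1, 16), FitSettings()
    )
    np.testing.assert_allclose(fit.W, [0.5, 0.5, 0.0], atol=0.02)


def test_factor_model_convex_combination_fits_exactly():
    """Treated intercepts equal to a convex combination of donor intercepts
    with a shared factor and no noise give a (near) zero pre-period MSPE."""
    n_months = 24
    factor = np.sin(np.linspace(0, 3, n_months))
    alphas = {"A": 0.7, "B": 1.3, "C": 2.0}
    w_true = np.array([0.6, 0.4, 0.0])
    series = {}
    for pid, a in alphas.items():
        series[pid] = {
            "ed_rate": 2.0 * a + factor,
            "adm_rate": a + 0.5 * factor,
            "readm_rate": 0.1 * a + 0.05 * factor,
        }
    treated_alpha = float(w_true @ np.array(list(alphas.values())))
    series["T"] = {
        "ed_rate": 2.0 * treated_alpha + factor,
        "adm_rate": treated_alpha + 0.5 * factor,
        "readm_rate": 0.1 * treated_alpha + 0.05 * factor,
    }
    panel = build_panel(series, n_months=n_months)
    fit = fit_synthetic_control(
        panel, simple_pool("ABC"),
        PredictorSpec(covariate_names=(), standardize=False), (1, 18), FitSettings()
    )
    assert fit.objective < 1e-8


def test_weights_stay_on_the_simplex(small_panel):
    panel, schedule = small_panel
    treated = schedule.treated_ids[0]
    pool = build_donor_pool(panel, schedule, treated, tolerance=0.4)
    fit = fit_synthetic_control(panel, pool, PredictorSpec(),
                                (1, schedule.join_month(treated) - 1), FAST_SETTINGS)
    assert np.all(fit.W >= -1e-9)
    assert abs(fit.W.sum() - 1) < 1e-6
    assert np.all(fit.V >= -1e-12)
    assert abs(fit.V.sum() - 1) < 1e-6


def test_nested_objective_not_worse_than_equal_v(small_panel):
    panel, schedule = small_panel
    treated = schedule.treated_ids[1]
    pool = build_donor_pool(panel, schedule, treated, tolerance=0.4)
    spec = PredictorSpec()
    pre = (1, schedule.join_month(treated) - 1)
    mats = assemble_matrices(panel, pool, spec, pre)
    V_equal = np.full(len(mats.X1), 1.0 / len(mats.X1))
    W_equal = solve_inner_weights(mats.X1, mats.X0, V_equal)
    fit = fit_synthetic_control(panel, pool, spec, pre,
                                FitSettings(n_multistarts=2, nm_maxiter=40))
    assert fit.objective <= outer_mspe(mats.Z1, mats.Z0, W_equal) + 1e-12


def test_nested_fit_matches_exhaustive_grid_oracle():
    """For a small pool the nested objective agrees with brute-force search
    over donor weights on a 0.01-step simplex grid."""
    rng = np.random.default_rng(21)
    series = {pid: random_outcome_series(rng, 18) for pid in ["T", "A", "B", "C"]}
    for pid in series:
        series[pid]["imd"] = float(rng.uniform(10, 40))
        series[pid]["list_size"] = float(rng.uniform(4000, 6000))
    panel = build_panel(series, n_months=18)
    spec = PredictorSpec(covariate_names=("imd", "list_size"), standardize=True)
    mats = assemble_matrices(panel, simple_pool("ABC"), spec, (1, 12))
    fit = fit_synthetic_control(panel, simple_pool("ABC"), spec, (1, 12),
                                FitSettings(n_multistarts=2, nm_maxiter=60))
    grid_best = min(outer_mspe(mats.Z1, mats.Z0, w) for w in grid_simplex(3, 0.01))
    assert abs(fit.objective - grid_best) <= 1e-3
    assert fit.objective <= grid_best + 1e-12


# ---------------------------------------------------------------- predict


def _manual_fit(donor_ids, W):
    return ScmFit(
        treated_id="T", donor_ids=list(donor_ids), W=np.asarray(W, dtype=float),
        V=np.array([1.0]), v_rows=["adm_rate"], pre_mspe={}, objective=0.0,
        converged=True,
    )


def test_predicted_path_equals_forced_donor():
    rng = np.random.default_rng(9)
    series = {pid: random_outcome_series(rng, 12) for pid in ["T", "A", "B"]}
    panel = build_panel(series, n_months=12)
    paths = predict_outcomes(_manual_fit(["A", "B"], [1.0, 0.0]), panel, (1, 12))
    np.testing.assert_allclose(paths["adm_rate"].to_numpy(), series["A"]["adm_rate"])


def test_predicted_path_is_a_pointwise_convex_combination():
    rng = np.random.default_rng(10)
    series = {pid: random_outcome_series(rng, 12) for pid in ["T", "A", "B", "C"]}
    panel = build_panel(series, n_months=12)
    donor_matrix = np.column_stack([series[p]["adm_rate"] for p in ["A", "B", "C"]])
    for _ in range(10):
        W = rng.dirichlet(np.ones(3))
        paths = predict_outcomes(_manual_fit(["A", "B", "C"], W), panel, (1, 12))
        values = paths["adm_rate"].to_numpy()
        assert np.all(values >= donor_matrix.min(axis=1) - 1e-12)
        assert np.all(values <= donor_matrix.max(axis=1) + 1e-12)
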