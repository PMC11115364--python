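"""Regressor construction, logistic fits, VIF, and forward simulation."""

import numpy as np
import pandas as pd
import pytest

import riskshift as rs
from riskshift.regression import _raw_regressors, BASE_REGRESSORS


def _toy_table():
    """Three analyzed trials of one PR participant with known history."""
    rows = [
        # block 1: poor; accept and win 25, then reject
        dict(trial_index=1, block_index=1, environment="poor", magnitude=25,
             probability=0.5, choice="accept", outcome=25.0),
        dict(trial_index=2, block_index=1, environment="poor", magnitude=40,
             probability=0.4, choice="reject", outcome=10.0),
        # block 2: rich
        dict(trial_index=3, block_index=2, environment="rich", magnitude=30,
             probability=0.6, choice="accept", outcome=0.0),
    ]
    for r in rows:
        r.update(participant_id=1, group="PR", experiment=1, catch_type="none", analyzed=True)
    return pd.DataFrame(rows)


def test_raw_regressors_match_hand_computation():
    raw = _raw_regressors(_toy_table()).set_index("trial_index")
    # static option regressors
    assert raw.loc[1, "EV"] == pytest.approx(12.5)
    assert raw.loc[1, "Risk"] == pytest.approx(25**2 * 0.25)
    assert raw.loc[1, "dp_c"] == pytest.approx(0.5 - 0.4)      # poor mean 0.4
    assert raw.loc[3, "dp_c"] == pytest.approx(0.6 - 0.6)      # rich mean 0.6
    assert raw.loc[1, "dp_p"] == 0.0                           # first block
    assert raw.loc[3, "dp_p"] == pytest.approx(0.6 - 0.4)      # rich after poor
    # history regressors reference the previous presented trial
    assert raw.loc[1, ["prev_choice", "prev_reward", "prev_success"]].tolist() == [0, 0, 0]
    assert raw.loc[2, "prev_choice"] == 1
    assert raw.loc[2, "prev_reward"] == 25.0
    assert raw.loc[2, "prev_success"] == 1
    assert raw.loc[3, "prev_choice"] == 0 and raw.loc[3, "prev_success"] == 0
    # accumulated reward before the current trial
    assert raw.loc[1, "cum_points"] == 0.0
    assert raw.loc[2, "cum_points"] == 25.0
    assert raw.loc[3, "cum_points"] == 35.0


def test_intermediate_after_rich_dp_p():
    rows = _toy_table()
    rows.loc[2, ["environment", "block_index"]] = ["intermediate", 2]
    rows.loc[1, ["environment", "block_index"]] = ["rich", 1]
    rows.loc[0, ["environment", "block_index"]] = ["rich", 1]
    raw = _raw_regressors(rows).set_index("trial_index")
    assert raw.loc[3, "dp_p"] == pytest.approx(0.5 - 0.6)


def test_unknown_environment_rejected():
    t = _toy_table()
    t.loc[0, "environment"] = "lush"
    with pytest.raises(ValueError, match="unknown environment"):
        rs.build_regressors(t)


def test_pooled_zscoring_invariants(small_kept):
    kept, _ = small_kept
    matrix = rs.build_regressors(kept)
    cols = matrix.full[list(BASE_REGRESSORS)]
    assert cols.mean().abs().max() < 1e-9
    assert np.allclose(cols.std(ddof=0), 1.0, atol=1e-9)
    # previous success implies previous choice (raw scale)
    raw = _raw_regressors(kept)
    assert (raw.loc[raw.prev_success == 1, "prev_choice"] == 1).all()
    # dp_p is constant within each participant x block
    assert (raw.groupby(["participant_id", "block_index"]).dp_p.nunique() == 1).all()


def test_zscoring_happens_before_subsetting(small_kept):
    kept, _ = small_kept
    matrix = rs.build_regressors(kept)
    fit_sub = rs.fit_logistic(matrix, subset=("EV", "Risk"))
    # the subset design uses the full-table z-scores: column stats preserved
    assert fit_sub.pooled_stats.equals(matrix.pooled_stats)


def _irls_logit(X, y, tol=1e-12):
    """Independent iteratively-reweighted-least-squares oracle."""
    X1 = np.column_stack([np.ones(len(y)), X])
    w = np.zeros(X1.shape[1])
    for _ in range(200):
        eta = X1 @ w
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / np.maximum(W, 1e-12)
        w_new = np.linalg.solve(X1.T @ (W[:, None] * X1), X1.T @ (W * z))
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    return w


def test_ml_fit_matches_irls_oracle(small_kept):
    kept, _ = small_kept
    matrix = rs.build_regressors(kept)
    subset = ("EV", "Risk", "dp_c", "dp_p")
    fit = rs.fit_logistic(matrix, subset=subset)
    X = matrix.data[list(subset)].to_numpy(float)
    y = matrix.data["accept"].to_numpy(float)
    oracle = _irls_logit(X, y)
    assert np.max(np.abs(fit.coefficients.to_numpy() - oracle)) < 1e-6
    # BIC bookkeeping
    k = len(subset) + 1
    assert fit.bic == pytest.approx(-2 * fit.loglik + k * np.log(len(y)))


def test_bic_prefers_generating_model_over_nested_subset(small_kept):
    """Responses generated from the full eight-regressor logistic model."""
    kept, _ = small_kept
    matrix = rs.build_regressors(kept)
    true_coefs = dict(EV=1.9, Risk=-0.9, dp_c=0.7, dp_p=0.5, prev_choice=0.4,
                      prev_reward=-0.05, prev_success=-0.1, acc_reward=-0.3)
    rng = np.random.default_rng(1)
    eta = 0.5 + sum(c * matrix.data[name] for name, c in true_coefs.items())
    synthetic = matrix.data.copy()
    synthetic["accept"] = (rng.random(len(eta)) < 1 / (1 + np.exp(-eta))).astype(int)
    mx = rs.RegressorMatrix(synthetic, matrix.pooled_stats, matrix.group_history_stats,
                            matrix.regressors)
    full = rs.fit_logistic(mx)
    sub = rs.fit_logistic(mx, subset=("EV", "Risk"))
    assert full.bic < sub.bic


def test_vif_orthogonal_duplicate_and_singular(rng):
    n = 400
    base = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    base = (base - base.mean()) / base.std(ddof=0)
    data = base.copy()
    data["accept"] = (rng.random(n) < 0.5).astype(int)
    data["participant_id"] = np.repeat(np.arange(20), 20)
    matrix = rs.RegressorMatrix(data, pd.DataFrame(), pd.DataFrame(), ("a", "b", "c"))
    v = rs.vif(matrix)
    assert (v < 1.1).all()
    data["dup"] = data["a"]
    matrix2 = rs.RegressorMatrix(data, pd.DataFrame(), pd.DataFrame(), ("a", "b", "c", "dup"))
    v2 = rs.vif(matrix2)
    assert v2["a"] == 1e6 and v2["dup"] == 1e6  # capped/flagged
    with pytest.raises(np.linalg.LinAlgError, match="singular"):
        rs.fit_logistic(matrix2)


def test_simulation_with_zero_coefficients_is_random(small_kept):
    kept, _ = small_kept
    matrix = rs.build_regressors(kept)
    fit = rs.fit_logistic(matrix)
    fit.coefficients[:] = 0.0
    sim = rs.simulate_from_fit(fit, ("PR",), 30, seed=0)
    q = (sim.choice == "accept").mean()
    assert abs(q - 0.5) < 3 * 0.5 / np.sqrt(len(sim))


def test_ablation_suite_drops_named_regressors(small_kept):
    kept, _ = small_kept
    matrix = rs.build_regressors(kept)
    out = rs.ablation_suite(matrix, drops=("dp_c", "acc_reward"), n_per_group=5, seed=0)
    assert set(out) == {"drop_dp_c", "drop_acc_reward"}
    fit, sim = out["drop_dp_c"]
    assert "dp_c" not in fit.subset and "dp_p" in fit.subset
    assert {"choice", "outcome"} <= set(sim.columns)


def test_extra_lag_regressors(small_kept):
    kept, _ = small_kept
    matrix = rs.build_regressors(kept, extra_lags=3)
    assert {"prev_choice2", "prev_choice3"} <= set(matrix.regressors)
    fit = rs.fit_logistic(matrix)
    assert "prev_choice3" in fit.coefficients.index
    # lag columns shift correctly (raw scale)
    raw = _raw_regressors(kept, extra_lags=3)
    one = raw[raw.participant_id == raw.participant_id.iloc[0]].sort_values("trial_index")
    acc = (one.choice == "accept").astype(float).to_numpy()
    assert np.allclose(one.prev_choice2.to_numpy()[2:], acc[:-2])
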