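"""Trial-history logistic regression and forward choice simulation.

Eight trial-level regressors explain the accept/reject choice: the option's
expected value (EV = m p) and outcome variance (Risk = m^2 p (1-p)); the
option's reward-probability deviation from the current environment's mean
(dp_c, local attractiveness); the current minus the previous environment's
mean probability (dp_p, relative improvement; 0 in the first block); the
previous trial's choice, reward, and their interaction (previous success);
and the reward accumulated before the current trial (z-scored within
participant). All regressors are computed for every presented trial, pooled
per experiment, and z-scored; models are fitted on analyzed trials only.

Fitted coefficients drive forward simulations over fresh schedules: static
regressors are standardized with the stored pooled statistics, while
history-dependent regressors are updated online from the simulated history
and pseudo-standardized with the corresponding group's stored mean/SD.
Ablations refit and re-simulate with named regressors dropped, or with
choices made two and three trials ago added as extra lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .bootstrap import two_tailed_onesample_test, percentile_ci
from .task import SURE_MAGNITUDE, build_environment, generate_experiment_schedule, is_analyzed_trial

BASE_REGRESSORS = (
    "EV",
    "Risk",
    "dp_c",
    "dp_p",
    "prev_choice",
    "prev_reward",
    "prev_success",
    "acc_reward",
)
_HISTORY = ("prev_choice", "prev_reward", "prev_success", "acc_reward",
            "prev_choice2", "prev_choice3")


@dataclass
class RegressorMatrix:
    """Z-scored design matrix plus the statistics needed for simulation."""

    data: pd.DataFrame                      # analyzed responded rows, z-scored columns
    pooled_stats: pd.DataFrame              # mean/sd used for the pooled z-scoring
    group_history_stats: pd.DataFrame       # per-group mean/sd of raw history regressors
    regressors: tuple[str, ...]
    full: pd.DataFrame = field(repr=False, default=None)   # every presented trial


def _raw_regressors(table: pd.DataFrame, extra_lags: int = 1) -> pd.DataFrame:
    env_means = {name: build_environment(name).mean_probability
                 for name in ("poor", "intermediate", "rich")}
    out = table.copy()
    out["EV"] = out["magnitude"] * out["probability"]
    out["Risk"] = out["magnitude"] ** 2 * out["probability"] * (1.0 - out["probability"])
    mean_p = out["environment"].map(env_means)
    if mean_p.isna().any():
        bad = out.loc[mean_p.isna(), "environment"].iloc[0]
        raise ValueError(f"unknown environment {bad!r}")
    out["dp_c"] = out["probability"] - mean_p
    frames = []
    for pid, g in out.groupby("participant_id", sort=True):
        g = g.sort_values("trial_index").copy()
        # previous-block mean probability per block (0 in the first block)
        block_means = g.groupby("block_index")["environment"].first().map(env_means)
        prev_means = block_means.shift(1)
        dp_p = (block_means - prev_means).fillna(0.0)
        g["dp_p"] = g["block_index"].map(dp_p)
        accept = (g["choice"] == "accept").astype(float)
        reward = g["outcome"].fillna(0.0)
        g["prev_choice"] = accept.shift(1, fill_value=0.0)
        for lag in range(2, extra_lags + 1):
            g[f"prev_choice{lag}"] = accept.shift(lag, fill_value=0.0)
        g["prev_reward"] = reward.shift(1, fill_value=0.0)
        g["prev_success"] = (accept * (reward > 0)).shift(1, fill_value=0.0)
        cum = reward.cumsum().shift(1, fill_value=0.0)
        g["cum_points"] = cum
        sd = cum.std(ddof=0)
        g["acc_reward"] = (cum - cum.mean()) / sd if sd > 0 else 0.0
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def build_regressors(table: pd.DataFrame, extra_lags: int = 1) -> RegressorMatrix:
    """Compute, pool, and z-score the regressors for one experiment's table.

    `extra_lags` > 1 adds previous-choice regressors at lags 2..extra_lags.
    """
    raw = _raw_regressors(table, extra_lags)
    regs = list(BASE_REGRESSORS) + [f"prev_choice{k}" for k in range(2, extra_lags + 1)]
    stats_rows = []
    for col in regs:
        mean, sd = raw[col].mean(), raw[col].std(ddof=0)
        sd = sd if sd > 0 else 1.0
        raw[col] = (raw[col] - mean) / sd
        stats_rows.append({"regressor": col, "mean": mean, "sd": sd})
    pooled = pd.DataFrame(stats_rows).set_index("regressor")
    hist_rows = []
    for group, g in raw.groupby("group", sort=True):
        for col in ("cum_points",):
            hist_rows.append(
                {"group": group, "quantity": col,
                 "mean": g[col].mean(), "sd": max(g[col].std(ddof=0), 1e-12)}
            )
    ghist = pd.DataFrame(hist_rows)
    fit_rows = raw[raw["analyzed"] & (raw["choice"] != "missing")].copy()
    fit_rows["accept"] = (fit_rows["choice"] == "accept").astype(int)
    return RegressorMatrix(fit_rows.reset_index(drop=True), pooled, ghist, tuple(regs), raw)


@dataclass
class RegressionFit:
    coefficients: pd.Series          # includes "intercept"
    loglik: float
    bic: float
    subset: tuple[str, ...]
    penalty: str
    n_obs: int
    separation_flag: bool
    pooled_stats: pd.DataFrame
    group_history_stats: pd.DataFrame
    p_values: pd.Series | None = None
    ci: pd.DataFrame | None = None
    boot_draws: pd.DataFrame | None = field(repr=False, default=None)


def _sk_fit(X: np.ndarray, y: np.ndarray, penalty: str, seed: int = 0):
    if penalty == "none":
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-10)
    elif penalty == "L1":
        # penalty strength by 5-fold cross-validated deviance
        model = LogisticRegressionCV(
            l1_ratios=(1.0,), solver="saga", Cs=10, cv=5,
            scoring="neg_log_loss", max_iter=5000, random_state=seed,
            use_legacy_attributes=False,
        )
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    model.fit(X, y)
    return np.concatenate([model.intercept_, model.coef_.ravel()])


def _loglik(coefs: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = coefs[0] + X @ coefs[1:]
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    matrix: RegressorMatrix,
    subset: tuple[str, ...] | None = None,
    penalty: str = "none",
    bootstrap_B: int = 0,
    seed: int = 0,
    m_tests: int | None = None,
) -> RegressionFit:
    """Pooled logistic fit of acceptance on the chosen regressor subset.

    With `bootstrap_B` > 0 the coefficients get participant-resampled 95%
    bounds and two-tailed one-sample bootstrap p-values against zero,
    Bonferroni-multiplied by the subset size (or `m_tests`).
    """
    subset = tuple(subset or matrix.regressors)
    df = matrix.data
    if df["accept"].nunique() < 2:
        raise ValueError("need at least 2 distinct responses")
    X = df[list(subset)].to_numpy(float)
    y = df["accept"].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix: collinear regressor subset")
    coefs = _sk_fit(X, y, penalty, seed)
    ll = _loglik(coefs, X, y)
    k = len(subset) + 1
    bic = -2.0 * ll + k * np.log(len(y))
    names = ["intercept"] + list(subset)
    fit = RegressionFit(
        pd.Series(coefs, index=names), ll, float(bic), subset, penalty, len(y),
        bool(np.any(np.abs(coefs) > 1e2)), matrix.pooled_stats, matrix.group_history_stats,
    )
    if bootstrap_B > 0:
        rng = np.random.default_rng(seed)
        groups = df.groupby("participant_id").indices
        pids = list(groups)
        draws = np.empty((bootstrap_B, k))
        for b in range(bootstrap_B):
            take = rng.integers(0, len(pids), len(pids))
            idx = np.concatenate([groups[pids[i]] for i in take])
            draws[b] = _sk_fit(X[idx], y[idx], penalty, seed)
        m = m_tests if m_tests is not None else len(subset)
        fit.boot_draws = pd.DataFrame(draws, columns=names)
        fit.p_values = pd.Series(
            {n: two_tailed_onesample_test(draws[:, j], coefs[j], 0.0, m)
             for j, n in enumerate(names)}
        )
        fit.ci = pd.DataFrame(
            {n: percentile_ci(draws[:, j]) for j, n in enumerate(names)},
            index=["lo", "hi"],
        ).T
    return fit


def vif(matrix: RegressorMatrix, subset: tuple[str, ...] | None = None) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j), capped at 1e6."""
    subset = tuple(subset or matrix.regressors)
    if len(subset) < 2:
        raise ValueError("VIF needs at least 2 regressors")
    X = matrix.data[list(subset)].to_numpy(float)
    out = {}
    for j, name in enumerate(subset):
        others = np.delete(X, j, axis=1)
        xj = X[:, j]
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(xj)), others]), xj, rcond=None
        )
        resid = xj - np.column_stack([np.ones(len(xj)), others]) @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((xj - xj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[name] = min(1.0 / max(1.0 - r2, 1e-6), 1e6)
    return pd.Series(out)


def simulate_from_fit(
    fit: RegressionFit,
    groups: tuple[str, ...] = ("PR", "RP"),
    n_per_group: int = 120,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-simulate choices over fresh schedules from fitted coefficients.

    Static regressors use the stored pooled z statistics; history regressors
    are built online from the simulated history and pseudo-standardized with
    the group's stored statistics.
    """
    rng = np.random.default_rng(seed)
    stats = fit.pooled_stats
    env_means = {name: build_environment(name).mean_probability
                 for name in ("poor", "intermediate", "rich")}
    ghist = fit.group_history_stats.set_index(["group", "quantity"])
    coefs = fit.coefficients
    rows = []
    pid = 0
    for group in groups:
        cum_stats = ghist.loc[(group, "cum_points")]
        for _ in range(n_per_group):
            pid += 1
            design = generate_experiment_schedule(group, rng)
            cum = 0.0
            prev = {"prev_choice": 0.0, "prev_choice2": 0.0, "prev_choice3": 0.0,
                    "prev_reward": 0.0, "prev_success": 0.0}
            t = 0
            prev_mean_p = None
            for block in design.blocks:
                env_mean = env_means[block.environment.name]
                dp_p_raw = 0.0 if prev_mean_p is None else env_mean - prev_mean_p
                for trial in block.trials:
                    t += 1
                    m_, p_ = float(trial.magnitude), float(trial.probability)
                    raw = {
                        "EV": m_ * p_,
                        "Risk": m_**2 * p_ * (1.0 - p_),
                        "dp_c": p_ - env_mean,
                        "dp_p": dp_p_raw,
                        "prev_choice": prev["prev_choice"],
                        "prev_choice2": prev["prev_choice2"],
                        "prev_choice3": prev["prev_choice3"],
                        "prev_reward": prev["prev_reward"],
                        "prev_success": prev["prev_success"],
                        "acc_reward": (cum - cum_stats["mean"]) / cum_stats["sd"],
                    }
                    eta = float(coefs["intercept"])
                    for name in fit.subset:
                        s = stats.loc[name]
                        eta += coefs[name] * (raw[name] - s["mean"]) / s["sd"]
                    p_acc = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
                    accept = rng.random() < p_acc
                    if accept:
                        outcome = float(trial.magnitude if rng.random() < p_ else 0)
                    else:
                        outcome = float(SURE_MAGNITUDE)
                    cum += outcome
                    prev["prev_choice3"] = prev["prev_choice2"]
                    prev["prev_choice2"] = prev["prev_choice"]
                    prev["prev_choice"] = 1.0 if accept else 0.0
                    prev["prev_reward"] = outcome
                    prev["prev_success"] = 1.0 if (accept and outcome > 0) else 0.0
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "experiment": design.experiment,
                            "block_index": block.block_index,
                            "trial_index": t,
                            "environment": block.environment.name,
                            "magnitude": trial.magnitude,
                            "probability": trial.probability,
                            "catch_type": trial.catch_type.value,
                            "analyzed": is_analyzed_trial(trial),
                            "choice": "accept" if accept else "reject",
                            "outcome": outcome,
                        }
                    )
                prev_mean_p = env_mean
    return pd.DataFrame(rows)


def ablation_suite(
    matrix: RegressorMatrix,
    drops: tuple[str, ...] = ("dp_c", "dp_p", "prev_choice", "acc_reward"),
    groups: tuple[str, ...] = ("PR", "RP"),
    n_per_group: int = 120,
    seed: int = 0,
) -> dict[str, tuple[RegressionFit, pd.DataFrame]]:
    """Refit with each named regressor dropped and forward-simulate each refit."""
    out = {}
    for name in drops:
        subset = tuple(r for r in matrix.regressors if r != name)
        fit = fit_logistic(matrix, subset)
        sim = simulate_from_fit(fit, groups, n_per_group, seed=seed)
        out[f"drop_{name}"] = (fit, sim)
    return out
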