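"""Fitness simulation: survival probability and mean reward versus risk preference.

Risk-sensitive foraging theory distinguishes two fitness criteria for an agent
facing 60 gambles drawn from an environment: the probability of accumulating at
least a survival threshold ("need"), and the mean accumulated reward. Choices
are generated from the risk-return utility with risk-aversiveness ``alpha``,
either through a sigmoid rule or in the deterministic utility-maximizing limit.

Under the mean-reward criterion the optimum is risk neutrality (alpha = 0)
regardless of environment or need: accepting exactly the gambles whose expected
value exceeds the sure 10 points maximizes the expected sum. Under the survival
criterion the optimum shifts toward risk proneness (alpha < 0) as the
environment worsens or the need rises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import SURE_MAGNITUDE, EnvironmentSpec

HORIZON = 60

#: Survival thresholds (points over a 60-trial horizon) for the three need levels.
NEED_THRESHOLDS = {"high": 850, "moderate": 1000, "low": 1150}


@dataclass(frozen=True)
class NeedCondition:
    label: str
    threshold: float
    horizon: int = HORIZON

    @classmethod
    def named(cls, label: str) -> "NeedCondition":
        return cls(label, NEED_THRESHOLDS[label])


def standard_needs() -> list[NeedCondition]:
    return [NeedCondition.named(k) for k in NEED_THRESHOLDS]


def _grid(env: EnvironmentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Non-catch (magnitude, probability) grid of the environment."""
    m, p = np.meshgrid(env.magnitudes, env.probabilities)
    return m.ravel().astype(float), p.ravel().astype(float)


def expected_reward_deterministic(env: EnvironmentSpec, alpha: float,
                                  horizon: int = HORIZON) -> float:
    """Analytic expected accumulated reward in the deterministic choice limit.

    The agent accepts a gamble iff its risk-return utility exceeds the sure
    10 points; each of the `horizon` gambles is an independent uniform draw
    from the environment's non-catch grid.
    """
    m, p = _grid(env)
    if m.size == 0:
        raise ValueError("environment grid is empty")
    u = m * p - alpha * m**2 * p * (1.0 - p)
    per_trial = np.where(u > SURE_MAGNITUDE, m * p, float(SURE_MAGNITUDE))
    return horizon * float(per_trial.mean())


def simulate_fitness_point(
    env: EnvironmentSpec,
    alpha: float,
    need: NeedCondition,
    rng: np.random.Generator,
    beta: float = 0.1,
    deterministic: bool = False,
    n_agents: int = 10_000,
) -> tuple[float, float]:
    """Monte-Carlo (survival probability, mean accumulated reward) at one alpha.

    Each agent faces `need.horizon` gambles drawn uniformly with replacement
    from the environment's non-catch grid; choices via risk-return utility with
    a sigmoid rule of inverse temperature `beta`, or via the deterministic
    utility-maximizing limit.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    m, p = _grid(env)
    if m.size == 0:
        raise ValueError("environment grid is empty")
    idx = rng.integers(0, m.size, size=(n_agents, need.horizon))
    mm, pp = m[idx], p[idx]
    du = (mm * pp - SURE_MAGNITUDE) - alpha * mm**2 * pp * (1.0 - pp)
    if deterministic:
        accept = du > 0
    else:
        accept = rng.random(du.shape) < 1.0 / (1.0 + np.exp(-np.clip(beta * du, -700, 700)))
    win = rng.random(du.shape) < pp
    payoff = np.where(accept, np.where(win, mm, 0.0), float(SURE_MAGNITUDE))
    totals = payoff.sum(axis=1)
    return float(np.mean(totals >= need.threshold)), float(totals.mean())


def default_alpha_grid(n: int = 41) -> np.ndarray:
    """Symmetric grid of risk-aversiveness values spanning [-0.02, 0.02]."""
    return np.linspace(-0.02, 0.02, n)


def fitness_curves(
    env: EnvironmentSpec,
    alpha_grid: np.ndarray,
    needs: list[NeedCondition],
    rng: np.random.Generator,
    beta: float = 0.1,
    deterministic: bool = False,
    n_agents: int = 10_000,
) -> pd.DataFrame:
    """Sweep alpha for each need level; tidy frame of survival and mean reward."""
    rows = []
    for need in needs:
        for alpha in alpha_grid:
            surv, mean_r = simulate_fitness_point(
                env, float(alpha), need, rng, beta=beta,
                deterministic=deterministic, n_agents=n_agents,
            )
            rows.append(
                {
                    "environment": env.name,
                    "need": need.label,
                    "threshold": need.threshold,
                    "alpha": float(alpha),
                    "survival_prob": surv,
                    "mean_reward": mean_r,
                }
            )
    return pd.DataFrame(rows)


def optimal_alpha(alpha_grid: np.ndarray, values: np.ndarray) -> float:
    """Grid argmax; ties broken toward smallest |alpha|, then the more negative."""
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("empty alpha grid")
    best = np.isclose(values, values.max())
    cand = alpha_grid[best]
    cand = cand[np.lexsort((cand, np.abs(cand)))]
    return float(cand[0])


def optimal_alpha_expected_reward(env: EnvironmentSpec,
                                  alpha_grid: np.ndarray | None = None,
                                  horizon: int = HORIZON) -> float:
    """Argmax of the analytic deterministic-limit expected reward over the grid."""
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    values = np.array([expected_reward_deterministic(env, a, horizon) for a in alpha_grid])
    return optimal_alpha(alpha_grid, values)
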