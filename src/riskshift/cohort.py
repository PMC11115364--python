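"""Synthetic cohort generator: trial tables with known ground truth.

Each simulated participant draws a baseline risk-aversiveness ``alpha0`` and an
inverse temperature ``beta`` from group-level distributions, then makes
accept/reject choices through the risk-return utility and a sigmoid rule with
a trial-varying effective risk-aversiveness

    alpha_t = alpha0 - env_effect * dp_c - past_effect * dp_p
              + acc_effect * z(accumulated reward),

where dp_c is the option's reward-probability deviation from the current
environment's mean, dp_p is the current minus the previous environment's mean
probability (0 in the first block), and z(.) standardizes the running reward
total against its expected trajectory. A perseveration bias is added to the
utility difference when the previous choice was an accept. With positive
effect weights this instantiates the empirical signatures the downstream
analyses target: more gambling in and after poor environments, and less
gambling as reward accumulates.

Attentive participants answer catch trials correctly with high probability
(lapse-style attention model); a configurable fraction of inattentive
participants answers catch trials at chance, tripping the catch-error
exclusion criterion. Non-responses are injected at a small per-trial rate and
recorded as missing choices with no reward.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .models import ModelSpec, UtilityParams, choice_probability
from .task import (
    SURE_MAGNITUDE,
    CatchType,
    generate_experiment_schedule,
    is_analyzed_trial,
)

# expected per-trial gain and mid-run spread used to standardize the running
# reward total online (points); see docs/methods.md
ACC_RATE = 20.0
ACC_SCALE = 150.0


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of a synthetic cohort (the study conditions)."""

    n_per_group: int = 120
    alpha0_mean: float = 1.8e-2
    alpha0_sd: float = 0.4e-2
    beta_mean: float = 0.5
    beta_sd: float = 0.1
    env_effect: float = 2.0e-2
    past_effect: float = 1.2e-2
    acc_effect: float = 0.1e-2
    perseveration: float = 1.0
    nonresponse_rate: float = 0.003
    inattentive_fraction: float = 0.15
    catch_accuracy: float = 0.98

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for name in ("nonresponse_rate", "inattentive_fraction", "catch_accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


_SIGMOID_SPEC = ModelSpec(family="risk_return", rule="sigmoid")


def generate_cohort(
    config: CohortConfig,
    groups: tuple[str, ...] = ("PR", "RP"),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format trial table plus its ground-truth sidecar.

    Returns
    -------
    table : DataFrame
        One row per presented trial (all participants of all `groups`).
    truth : DataFrame
        Per-participant generating parameters (alpha0, beta, inattentive flag)
        together with the shared effect weights.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    pid = 0
    for group in groups:
        for _ in range(config.n_per_group):
            pid += 1
            alpha0 = rng.normal(config.alpha0_mean, config.alpha0_sd)
            if config.beta_sd > 0:
                shape = (config.beta_mean / config.beta_sd) ** 2
                rate = config.beta_mean / config.beta_sd**2
                beta = rng.gamma(shape, 1.0 / rate)
            else:
                beta = config.beta_mean
            inattentive = rng.random() < config.inattentive_fraction
            truth_rows.append(
                {"participant_id": pid, "group": group, "alpha0": alpha0,
                 "beta": beta, "inattentive": inattentive}
            )
            design = generate_experiment_schedule(group, rng)
            acc = 0.0
            prev_accept = 0
            t = 0
            prev_mean_p: float | None = None
            for block in design.blocks:
                env = block.environment
                dp_p = 0.0 if prev_mean_p is None else env.mean_probability - prev_mean_p
                for trial in block.trials:
                    t += 1
                    if rng.random() < config.nonresponse_rate:
                        choice, outcome = "missing", np.nan
                    elif trial.catch_type != CatchType.NONE:
                        correct = (
                            rng.random() < 0.5 if inattentive
                            else rng.random() < config.catch_accuracy
                        )
                        accept = (trial.catch_type == CatchType.ALWAYS_ACCEPT) == correct
                        choice = "accept" if accept else "reject"
                    else:
                        dp_c = trial.probability - env.mean_probability
                        z_acc = (acc - ACC_RATE * (t - 1)) / ACC_SCALE
                        alpha_t = (
                            alpha0
                            - config.env_effect * dp_c
                            - config.past_effect * dp_p
                            + config.acc_effect * z_acc
                        )
                        params = UtilityParams(alpha=alpha_t, beta=beta)
                        p_acc = choice_probability(_SIGMOID_SPEC, params, trial)
                        # perseveration bias enters the choice logit directly
                        logit = np.log(p_acc / (1 - p_acc)) if 0 < p_acc < 1 else (
                            np.inf if p_acc >= 1 else -np.inf
                        )
                        logit = logit + beta * config.perseveration * prev_accept
                        p_acc = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
                        choice = "accept" if rng.random() < p_acc else "reject"
                    if choice == "accept":
                        outcome = float(
                            trial.magnitude if rng.random() < trial.probability else 0
                        )
                    elif choice == "reject":
                        outcome = float(SURE_MAGNITUDE)
                    if choice != "missing":
                        acc += outcome
                        prev_accept = 1 if choice == "accept" else 0
                    else:
                        prev_accept = 0
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "experiment": design.experiment,
                            "block_index": block.block_index,
                            "trial_index": t,
                            "environment": env.name,
                            "magnitude": trial.magnitude,
                            "probability": trial.probability,
                            "catch_type": trial.catch_type.value,
                            "analyzed": is_analyzed_trial(trial),
                            "choice": choice,
                            "outcome": outcome,
                        }
                    )
                prev_mean_p = env.mean_probability
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    for key, val in asdict(config).items():
        truth.attrs[key] = val
    return table, truth
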