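"""Decision models: utility families and choice rules.

Three utility families describe the subjective value of a gamble paying ``m``
points with probability ``p``:

* risk-return (mean-variance):  U = m p - alpha * m^2 p (1 - p), where the
  risk-aversiveness ``alpha`` penalizes outcome variance (alpha > 0 is
  risk-averse, alpha < 0 risk-prone);
* multiplicative prospect-theory form:  U = v(m) * pi(p) with value function
  v(m) = m^lambda and Prelec probability weighting
  pi(p) = exp(-(-log p)^gamma);
* additive form:  U = (1 - w_p) * v~(m) + w_p * pi(p), where v~(m) is v
  normalized by its value at the largest design magnitude (65) so both terms
  lie in (0, 1].

Acceptance probability comes from a sigmoid rule
``1 / (1 + exp(-beta * (U_gamble - U_sure)))`` or from an approach-avoidance
rule that shifts the sigmoid's floor (eta > 0) or ceiling (eta < 0) by a bias
``eta`` in [-1, 1]. Excluded parameters (lambda, gamma) are fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import SURE_MAGNITUDE, MAGNITUDES, ExperimentDesign, GambleOption, is_analyzed_trial

MAX_MAGNITUDE = max(MAGNITUDES)

FAMILIES = ("risk_return", "multiplicative", "additive")
RULES = ("sigmoid", "approach_avoidance")


@dataclass(frozen=True)
class ModelSpec:
    """A utility family x choice rule, with optional lambda/gamma inclusion."""

    family: str = "risk_return"
    include_lambda: bool = True
    include_gamma: bool = True
    rule: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the free parameters, in a fixed fitting order."""
        names = ["beta"]
        if self.family == "risk_return":
            names.append("alpha")
        else:
            if self.include_lambda:
                names.append("lam")
            if self.include_gamma:
                names.append("gamma")
            if self.family == "additive":
                names.append("w_p")
        if self.rule == "approach_avoidance":
            names.append("eta")
        return tuple(names)

    @property
    def label(self) -> str:
        parts = [self.family]
        if self.family != "risk_return":
            inc = [n for n, f in (("lam", self.include_lambda), ("gam", self.include_gamma)) if f]
            parts.append("+".join(inc) if inc else "base")
        parts.append(self.rule)
        return "/".join(parts)


@dataclass(frozen=True)
class UtilityParams:
    """Parameter vector; range constraints are enforced on construction."""

    alpha: float = 0.0       # risk-aversiveness (risk-return family)
    beta: float = 1.0        # inverse temperature, > 0
    gamma: float = 1.0       # Prelec probability-weighting exponent, > 0
    lam: float = 1.0         # value-function exponent, > 0
    w_p: float = 0.5         # probability weight (additive family), in [0, 1]
    eta: float = 0.0         # approach-avoidance bias, in [-1, 1]

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.lam <= 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")
        if not 0.0 <= self.w_p <= 1.0:
            raise ValueError(f"w_p must lie in [0, 1], got {self.w_p}")
        if not -1.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [-1, 1], got {self.eta}")

    def with_values(self, **kwargs: float) -> "UtilityParams":
        return replace(self, **kwargs)


def prelec_weight(p, gamma: float):
    """Prelec probability weighting pi(p) = exp(-(-log p)^gamma); pi(0) = 0 by limit."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    with np.errstate(divide="ignore"):
        out[pos] = np.exp(-np.power(-np.log(p[pos]), gamma))
    out = np.where(p >= 1.0, 1.0, out)
    return out if out.ndim else float(out)


def utility(spec: ModelSpec, params: UtilityParams, m, p):
    """Subjective utility of a gamble (m, p) under the given family."""
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    lam = params.lam if (spec.include_lambda or spec.family == "risk_return") else 1.0
    gamma = params.gamma if spec.include_gamma else 1.0
    if spec.family == "risk_return":
        u = m * p - params.alpha * m**2 * p * (1.0 - p)
    elif spec.family == "multiplicative":
        u = np.power(m, lam) * prelec_weight(p, gamma)
    else:  # additive, value term normalized by the design maximum
        v = np.power(m, lam) / MAX_MAGNITUDE**lam
        u = (1.0 - params.w_p) * v + params.w_p * prelec_weight(p, gamma)
    return u if np.ndim(u) else float(u)


def delta_utility(spec: ModelSpec, params: UtilityParams, trial: GambleOption | None = None,
                  m=None, p=None):
    """Excess utility of accepting the gamble over the sure 10 points."""
    if trial is not None:
        m, p = trial.magnitude, trial.probability
    return utility(spec, params, m, p) - utility(spec, params, SURE_MAGNITUDE, 1.0)


def _sigmoid(x):
    # clip keeps exp from overflowing; saturates far in the tails anyway
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def choice_probability(spec: ModelSpec, params: UtilityParams, trial: GambleOption | None = None,
                       m=None, p=None):
    """Probability of accepting the gamble under the spec's choice rule."""
    du = delta_utility(spec, params, trial, m=m, p=p)
    base = _sigmoid(params.beta * np.asarray(du, dtype=float))
    if spec.rule == "approach_avoidance":
        eta = params.eta
        if eta >= 0:
            base = (1.0 - eta) * base + eta
        else:
            base = (1.0 + eta) * base
    return base if np.ndim(base) else float(base)


def simulate_choices(
    spec: ModelSpec,
    participant_params: list[UtilityParams],
    schedules: list[ExperimentDesign],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate accept/reject choices and sampled outcomes for each participant.

    One parameter set and one schedule per participant. Accepted gambles pay
    the magnitude with the stated probability (else 0); rejected gambles pay
    the sure 10 points. Returns a long-format trial table.
    """
    if len(participant_params) != len(schedules):
        raise ValueError("need one parameter set per schedule")
    rows = []
    for pid, (params, design) in enumerate(zip(participant_params, schedules), start=1):
        t = 0
        for block in design.blocks:
            for trial in block.trials:
                t += 1
                p_acc = choice_probability(spec, params, trial)
                accept = rng.random() < p_acc
                if accept:
                    outcome = trial.magnitude if rng.random() < trial.probability else 0
                else:
                    outcome = SURE_MAGNITUDE
                rows.append(
                    {
                        "participant_id": pid,
                        "group": design.group,
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
    return pd.DataFrame(rows)
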