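"""Task structure: environments, blocks, and group schedules.

The task presents a series of independent accept/reject gambles. Each gamble
pays ``magnitude`` points with probability ``probability`` (and nothing
otherwise); rejecting always pays a sure 10 points. Blocks differ only in the
reward-probability distribution ("environmental richness"):

=============  =========================  ==============
environment    reward probabilities       mean richness
=============  =========================  ==============
poor           0.2, 0.3, 0.4, 0.5, 0.6    0.4
intermediate   0.4, 0.5, 0.6              0.5
rich           0.4, 0.5, 0.6, 0.7, 0.8    0.6
=============  =========================  ==============

Reward magnitudes are always {15, 20, ..., 65}. Every (probability, magnitude)
grid pair occurs exactly once per block, plus catch trials with a dominant
answer: magnitude-10 gambles (always better to reject) and probability-1
gambles (always better to accept). Poor/rich blocks hold 8 reject-catch and 3
accept-catch trials (66 trials total); intermediate blocks hold 3 + 3
(39 trials total). Trial order is shuffled uniformly per participant.

Only trials whose gamble parameters occur in every environment enter the
analyses: non-catch trials with probability in {0.4, 0.5, 0.6} and magnitude
above 10 ("analyzed trials", 33 per block).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

SURE_MAGNITUDE = 10
MAGNITUDES = tuple(range(15, 70, 5))
ANALYZED_PROBABILITIES = (0.4, 0.5, 0.6)


class CatchType(str, enum.Enum):
    NONE = "none"
    ALWAYS_REJECT = "always_reject"
    ALWAYS_ACCEPT = "always_accept"


@dataclass(frozen=True)
class GambleOption:
    """One gamble: pays `magnitude` with `probability`, else nothing."""

    magnitude: int
    probability: float
    catch_type: CatchType = CatchType.NONE

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValueError(f"magnitude must be positive, got {self.magnitude}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must lie in [0, 1], got {self.probability}")
        if self.catch_type == CatchType.ALWAYS_REJECT:
            if not (self.magnitude == SURE_MAGNITUDE and self.probability < 1):
                raise ValueError("reject-catch trials require magnitude 10 and probability < 1")
        elif self.catch_type == CatchType.ALWAYS_ACCEPT:
            if not (self.probability == 1 and self.magnitude > SURE_MAGNITUDE):
                raise ValueError("accept-catch trials require probability 1 and magnitude > 10")


@dataclass(frozen=True)
class EnvironmentSpec:
    """A named reward-probability distribution plus catch-trial composition."""

    name: str
    probabilities: tuple[float, ...]
    magnitudes: tuple[int, ...]
    n_catch_reject: int
    n_catch_accept: int

    @property
    def mean_probability(self) -> float:
        return float(np.mean(self.probabilities))

    @property
    def n_trials(self) -> int:
        return len(self.probabilities) * len(self.magnitudes) + self.n_catch_reject + self.n_catch_accept


_ENVIRONMENTS = {
    "poor": EnvironmentSpec("poor", (0.2, 0.3, 0.4, 0.5, 0.6), MAGNITUDES, 8, 3),
    "intermediate": EnvironmentSpec("intermediate", (0.4, 0.5, 0.6), MAGNITUDES, 3, 3),
    "rich": EnvironmentSpec("rich", (0.4, 0.5, 0.6, 0.7, 0.8), MAGNITUDES, 8, 3),
}

#: Block orders per experimental group.
GROUP_ENVIRONMENTS = {
    "PR": ("poor", "rich"),
    "RP": ("rich", "poor"),
    "IPI": ("intermediate", "poor", "intermediate"),
    "IRI": ("intermediate", "rich", "intermediate"),
}

#: Which experiment each group belongs to.
GROUP_EXPERIMENT = {"PR": 1, "RP": 1, "IPI": 2, "IRI": 2}


@dataclass(frozen=True)
class BlockSchedule:
    environment: EnvironmentSpec
    trials: tuple[GambleOption, ...]
    block_index: int


@dataclass(frozen=True)
class ExperimentDesign:
    experiment: int
    group: str
    blocks: tuple[BlockSchedule, ...] = field(default_factory=tuple)

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)


def build_environment(name: str) -> EnvironmentSpec:
    """Return the named environment specification.

    Raises
    ------
    KeyError
        If `name` is not one of poor / intermediate / rich.
    """
    try:
        return _ENVIRONMENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown environment {name!r}; expected one of {sorted(_ENVIRONMENTS)}"
        ) from None


def generate_block(
    env: EnvironmentSpec, rng: np.random.Generator, block_index: int = 0
) -> BlockSchedule:
    """Build one block: each grid pair once, plus catch trials, uniformly shuffled.

    Reject-catch probabilities are drawn (with replacement) from the
    environment's probability set; accept-catch magnitudes from the magnitude
    set, so catch trials look locally typical.
    """
    trials: list[GambleOption] = [
        GambleOption(m, p)
        for p in env.probabilities
        for m in env.magnitudes
    ]
    catch_ps = rng.choice(env.probabilities, size=env.n_catch_reject, replace=True)
    trials += [GambleOption(SURE_MAGNITUDE, float(p), CatchType.ALWAYS_REJECT) for p in catch_ps]
    catch_ms = rng.choice(env.magnitudes, size=env.n_catch_accept, replace=True)
    trials += [GambleOption(int(m), 1.0, CatchType.ALWAYS_ACCEPT) for m in catch_ms]
    order = rng.permutation(len(trials))
    return BlockSchedule(env, tuple(trials[i] for i in order), block_index)


def generate_experiment_schedule(group: str, rng: np.random.Generator) -> ExperimentDesign:
    """Build one participant's full schedule for the given group (PR/RP/IPI/IRI)."""
    if group not in GROUP_ENVIRONMENTS:
        raise KeyError(f"unknown group {group!r}; expected one of {sorted(GROUP_ENVIRONMENTS)}")
    blocks = tuple(
        generate_block(build_environment(name), rng, block_index=i)
        for i, name in enumerate(GROUP_ENVIRONMENTS[group], start=1)
    )
    return ExperimentDesign(GROUP_EXPERIMENT[group], group, blocks)


def is_analyzed_trial(trial: GambleOption) -> bool:
    """True for non-catch trials common to all environments (p in {.4,.5,.6}, m > 10)."""
    return (
        trial.catch_type == CatchType.NONE
        and any(np.isclose(trial.probability, p) for p in ANALYZED_PROBABILITIES)
        and trial.magnitude > SURE_MAGNITUDE
    )
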