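"""Participant-level bootstrap: distributions, CIs, and hypothesis tests.

Resampling is always at the participant level: a bootstrap sample draws N
participants with replacement and recomputes the pooled statistic (e.g. the
pooled acceptance proportion) on the resampled set. The one-tailed
difference test for H0: q_A - q_B <= 0 builds the null distribution from
recentered bootstrap draws,

    D_null_b = (q_A_b - q_A) - (q_B_b - q_B),

and reports p = (1 + #{D_null_b > D}) / (1 + B). The two-tailed one-sample
test against a null value recenters the draws at the observed statistic and
doubles the smaller tail, with the same +1 smoothing; Bonferroni correction
multiplies by the number of tests and caps at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .descriptive import participant_counts

DEFAULT_B = 9_999


@dataclass(frozen=True)
class BootstrapResult:
    observed: float
    p_value: float
    ci_low: float
    ci_high: float
    B: int
    null_draws: np.ndarray = field(repr=False, default=None)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def bootstrap_proportion(
    accepts: np.ndarray, choices: np.ndarray, B: int = DEFAULT_B, seed=0
) -> np.ndarray:
    """B pooled-proportion draws from participant-level resampling (vectorized)."""
    accepts = np.asarray(accepts, dtype=float)
    choices = np.asarray(choices, dtype=float)
    n = accepts.size
    if n == 0:
        raise ValueError("empty participant set")
    # canonical participant order makes the draws invariant to input ordering
    order = np.lexsort((choices, accepts))
    accepts, choices = accepts[order], choices[order]
    rng = _as_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    return accepts[idx].sum(axis=1) / choices[idx].sum(axis=1)


def bootstrap_distribution(
    data: Sequence, statistic: Callable[[Sequence], float], B: int = DEFAULT_B, seed=0
) -> np.ndarray:
    """Generic participant-level bootstrap of an arbitrary pooled statistic."""
    n = len(data)
    if n == 0:
        raise ValueError("empty participant set")
    rng = _as_rng(seed)
    draws = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        draws[b] = statistic([data[i] for i in idx])
    return draws


def percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile bounds of a bootstrap distribution."""
    lo = (1.0 - level) / 2.0
    return float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo))


def one_tailed_diff_test_counts(
    accepts_a, choices_a, accepts_b, choices_b, B: int = DEFAULT_B, seed=0
) -> BootstrapResult:
    """One-tailed bootstrap test of H0: q_A - q_B <= 0 from per-participant counts."""
    rng = _as_rng(seed)
    accepts_a = np.asarray(accepts_a, float)
    choices_a = np.asarray(choices_a, float)
    accepts_b = np.asarray(accepts_b, float)
    choices_b = np.asarray(choices_b, float)
    q_a = accepts_a.sum() / choices_a.sum()
    q_b = accepts_b.sum() / choices_b.sum()
    d = q_a - q_b
    draws_a = bootstrap_proportion(accepts_a, choices_a, B, rng)
    draws_b = bootstrap_proportion(accepts_b, choices_b, B, rng)
    null = (draws_a - q_a) - (draws_b - q_b)
    p = (1.0 + np.sum(null > d)) / (1.0 + B)
    ci = percentile_ci(draws_a - draws_b)
    return BootstrapResult(float(d), float(p), ci[0], ci[1], B, null)


def one_tailed_diff_test(table_a, table_b, B: int = DEFAULT_B, seed=0) -> BootstrapResult:
    """Table-level wrapper of the one-tailed pooled-acceptance difference test."""
    acc_a, ch_a = participant_counts(table_a)
    acc_b, ch_b = participant_counts(table_b)
    return one_tailed_diff_test_counts(acc_a, ch_a, acc_b, ch_b, B=B, seed=seed)


def two_tailed_onesample_test(
    draws: np.ndarray, observed: float, null_value: float = 0.0, m_tests: int = 1
) -> float:
    """Two-tailed one-sample bootstrap p-value with Bonferroni correction.

    The bootstrap draws are recentered at the observed statistic to form the
    null; the p-value doubles the smaller tail (with +1 smoothing), is
    multiplied by `m_tests`, and capped at 1.
    """
    draws = np.asarray(draws, dtype=float)
    B = draws.size
    shift = observed - null_value
    centered = draws - observed
    p_hi = (1.0 + np.sum(centered >= shift)) / (1.0 + B)
    p_lo = (1.0 + np.sum(centered <= -shift)) / (1.0 + B)
    p = 2.0 * min(p_hi, p_lo) * m_tests
    return float(min(p, 1.0))
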