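"""Exclusion criteria, acceptance proportions, moving averages, curve fits.

Participants are excluded if they (1) did not complete their group's design,
(2) failed to respond on at least 5% of presented trials, (3) gave one
identical response on every trial, or (4) erred on more than 10% of catch
trials. All remaining analyses use analyzed trials only (non-catch,
probability in {0.4, 0.5, 0.6}, magnitude > 10) with missing responses
dropped.

The group-level proportion of gambles accepted pools choices over
participants: q = (sum of accepts) / (sum of choices). The time-resolved
variant averages accept and choice counts over a +/-k trial window
(window size 5 for the default k = 2), dropping indices within k of either
end of the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import GROUP_ENVIRONMENTS, build_environment

EXCLUSION_REASONS = (
    "incomplete",
    "nonresponse_ge_5pct",
    "constant_response",
    "catch_error_gt_10pct",
)


def expected_design_length(group: str) -> int:
    return sum(build_environment(name).n_trials for name in GROUP_ENVIRONMENTS[group])


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four a-priori exclusion criteria.

    Returns the kept sub-table and a per-participant report with a ``kept``
    flag and the list of failed criteria.
    """
    if "catch_type" not in table.columns:
        raise ValueError("trial table lacks the catch_type column required for exclusions")
    reports = []
    kept_ids = []
    for pid, sub in table.groupby("participant_id", sort=True):
        group = sub["group"].iloc[0]
        reasons = []
        if len(sub) < expected_design_length(group):
            reasons.append("incomplete")
        responded = sub["choice"] != "missing"
        if (~responded).mean() >= 0.05:
            reasons.append("nonresponse_ge_5pct")
        answered = sub.loc[responded, "choice"]
        if len(answered) > 0 and answered.nunique() == 1:
            reasons.append("constant_response")
        catch = sub[sub["catch_type"] != "none"]
        if len(catch) > 0:
            errors = (
                ((catch["catch_type"] == "always_reject") & (catch["choice"] == "accept"))
                | ((catch["catch_type"] == "always_accept") & (catch["choice"] == "reject"))
            ).sum()
            if errors / len(catch) > 0.10:
                reasons.append("catch_error_gt_10pct")
        reports.append({"participant_id": pid, "kept": not reasons, "reasons": reasons})
        if not reasons:
            kept_ids.append(pid)
    report = pd.DataFrame(reports)
    kept = table[table["participant_id"].isin(kept_ids)].reset_index(drop=True)
    return kept, report


def _analyzed_responses(table: pd.DataFrame) -> pd.DataFrame:
    sub = table[table["analyzed"] & (table["choice"] != "missing")].copy()
    sub["accept"] = (sub["choice"] == "accept").astype(int)
    return sub


def pooled_acceptance(table: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Pooled proportion of gambles accepted, optionally per grouping keys."""
    sub = _analyzed_responses(table)
    if by:
        out = (
            sub.groupby(by, sort=True)["accept"]
            .agg(n_accept="sum", n_choices="count")
            .reset_index()
        )
    else:
        out = pd.DataFrame(
            [{"n_accept": int(sub["accept"].sum()), "n_choices": int(len(sub))}]
        )
    if (out["n_choices"] == 0).any() or out.empty:
        raise ValueError("no analyzed choices in at least one cell")
    out["q"] = out["n_accept"] / out["n_choices"]
    return out


def participant_acceptance(table: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Per-participant proportion of gambles accepted."""
    keys = ["participant_id"] + (by or [])
    return pooled_acceptance(table, by=keys)


def participant_counts(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant (accepts, choices) count arrays over analyzed trials."""
    per = participant_acceptance(table)
    return per["n_accept"].to_numpy(float), per["n_choices"].to_numpy(float)


def moving_average_acceptance(table: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Windowed pooled acceptance per trial index, per group.

    Accept and choice counts at each trial index are summed over the window
    [i-k, i+k]; indices within k of either end are omitted.
    """
    sub = _analyzed_responses(table)
    frames = []
    for group, g in sub.groupby("group", sort=True):
        t_max = int(table.loc[table["group"] == group, "trial_index"].max())
        counts = (
            g.groupby("trial_index")["accept"]
            .agg(N="sum", M="count")
            .reindex(range(1, t_max + 1), fill_value=0)
        )
        win = counts.rolling(2 * k + 1, center=True, min_periods=2 * k + 1).sum()
        win = win.dropna()
        win = win[win["M"] > 0]
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "trial_index": win.index,
                    "q": win["N"] / win["M"],
                    "n_accept": win["N"].astype(int),
                    "n_choices": win["M"].astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CurveFit:
    intercept: float
    slope: float
    converged: bool
    separation_flag: bool


def fit_acceptance_curve(table: pd.DataFrame, on: str = "magnitude") -> CurveFit:
    """Binomial-logit fit of acceptance on magnitude (or probability).

    Perfect or quasi-perfect separation is reported through the flag rather
    than raised.
    """
    sub = _analyzed_responses(table)
    if sub[on].nunique() < 2:
        raise ValueError(f"need at least two distinct {on} levels")
    X = sm.add_constant(sub[on].to_numpy(float))
    model = sm.GLM(sub["accept"].to_numpy(float), X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100)
        converged = bool(res.converged)
        params = res.params
    except Exception:
        converged, params = False, np.array([np.nan, np.nan])
    separation = bool(not converged or np.any(np.abs(params) > 1e3))
    return CurveFit(float(params[0]), float(params[1]), converged, separation)
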