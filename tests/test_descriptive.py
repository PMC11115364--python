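"""Exclusions, pooled/per-participant acceptance, moving averages, curve fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riskshift as rs
from riskshift.descriptive import moving_average_acceptance, participant_acceptance


def _trial_rows(pid, choices, group="PR", catch=None, probs=None, analyzed=None):
    """Minimal rows for one participant; choices is a string of a/r/m."""
    n = len(choices)
    catch = catch or ["none"] * n
    probs = probs or [0.5] * n
    rows = []
    for t, (c, ct, p) in enumerate(zip(choices, catch, probs), start=1):
        choice = {"a": "accept", "r": "reject", "m": "missing"}[c]
        rows.append(
            dict(
                participant_id=pid, group=group, experiment=1, block_index=1,
                trial_index=t, environment="poor", magnitude=10 if ct == "always_reject" else 20,
                probability=1.0 if ct == "always_accept" else p,
                catch_type=ct,
                analyzed=(ct == "none" and p in (0.4, 0.5, 0.6)) if analyzed is None else analyzed[t - 1],
                choice=choice,
                outcome=np.nan if choice == "missing" else (10.0 if choice == "reject" else 20.0),
            )
        )
    return rows


def _full_length(choices_catch, choices_rest):
    """132-trial PR-length sequences: 22 catch trials then 110 ordinary ones."""
    return choices_catch + choices_rest, ["always_reject"] * 22 + ["none"] * 110


def test_catch_error_exclusion_at_3_of_22():
    # 3 errors on 22 catch trials = 13.6% > 10% -> excluded
    choices, catch = _full_length("a" * 3 + "r" * 19, "ar" * 55)
    rows = _trial_rows(1, choices, catch=catch)
    ok, _ = _full_length("r" * 22, "ar" * 55)
    rows += _trial_rows(2, ok, catch=catch)
    table = pd.DataFrame(rows)
    _, report = rs.apply_exclusions(table)
    r1 = report.set_index("participant_id").loc[1]
    assert not r1.kept and r1.reasons == ["catch_error_gt_10pct"]
    # 2 errors on 22 (9.1%) is tolerated
    choices, catch = _full_length("a" * 2 + "r" * 20, "ar" * 55)
    _, report = rs.apply_exclusions(pd.DataFrame(_trial_rows(1, choices, catch=catch)))
    assert report.iloc[0].kept


def test_constant_response_and_nonresponse_exclusions():
    c1, catch = _full_length("a" * 22, "a" * 110)           # one identical response
    c2, _ = _full_length("r" * 22, "m" * 7 + "ar" * 51 + "a")  # 7/132 = 5.3% missing
    c3, _ = _full_length("r" * 22, "ar" * 55)
    rows = (_trial_rows(1, c1, catch=catch) + _trial_rows(2, c2, catch=catch)
            + _trial_rows(3, c3, catch=catch))
    _, report = rs.apply_exclusions(pd.DataFrame(rows))
    report = report.set_index("participant_id")
    assert "constant_response" in report.loc[1].reasons
    assert "nonresponse_ge_5pct" in report.loc[2].reasons
    assert report.loc[3].kept


def test_attentive_complete_participant_kept(small_kept):
    kept, report = small_kept
    assert report[report.kept].reasons.map(len).eq(0).all()
    assert set(kept.participant_id) == set(report[report.kept].participant_id)


def test_incomplete_participant_excluded(small_cohort):
    table, _ = small_cohort
    pid = table.participant_id.iloc[0]
    clipped = pd.concat(
        [table[table.participant_id != pid],
         table[(table.participant_id == pid) & (table.trial_index <= 100)]]
    )
    _, report = rs.apply_exclusions(clipped)
    assert "incomplete" in report.set_index("participant_id").loc[pid].reasons


def test_exclusions_require_catch_column(small_cohort):
    table, _ = small_cohort
    with pytest.raises(ValueError, match="catch_type"):
        rs.apply_exclusions(table.drop(columns="catch_type"))


def test_pooled_acceptance_examples():
    rows = _trial_rows(1, "aaar") + _trial_rows(2, "arrr")
    q = rs.pooled_acceptance(pd.DataFrame(rows))
    assert q.loc[0, "q"] == pytest.approx(0.5)  # (3+1)/8
    one = rs.pooled_acceptance(pd.DataFrame(_trial_rows(1, "aaar")))
    assert one.loc[0, "q"] == pytest.approx(0.75)
    allacc = rs.pooled_acceptance(pd.DataFrame(_trial_rows(1, "aaaa")))
    assert allacc.loc[0, "q"] == 1.0


def test_pooled_acceptance_rejects_empty_cells():
    rows = _trial_rows(1, "mmmm")
    with pytest.raises(ValueError, match="no analyzed choices"):
        rs.pooled_acceptance(pd.DataFrame(rows))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.sampled_from("arm"), min_size=1, max_size=30), st.integers(1, 4))
def test_pooled_acceptance_equals_brute_force(choices, n_participants):
    """Oracle equivalence: pooled q equals direct counting over raw rows."""
    rows = []
    for pid in range(1, n_participants + 1):
        rows += _trial_rows(pid, "".join(choices))
    table = pd.DataFrame(rows)
    accepts = rejects = 0
    for _, r in table.iterrows():
        if r.analyzed and r.choice == "accept":
            accepts += 1
        elif r.analyzed and r.choice == "reject":
            rejects += 1
    if accepts + rejects == 0:
        return
    assert rs.pooled_acceptance(table).loc[0, "q"] == pytest.approx(accepts / (accepts + rejects))


def test_participant_vs_pooled_acceptance():
    # equal denominators: mean of participant q equals pooled q
    rows = _trial_rows(1, "aaar") + _trial_rows(2, "arrr")
    per = participant_acceptance(pd.DataFrame(rows))
    assert per.q.mean() == pytest.approx(0.5)
    # unequal denominators: they differ
    rows = _trial_rows(1, "aaaaaaar") + _trial_rows(2, "rr")
    table = pd.DataFrame(rows)
    pooled = rs.pooled_acceptance(table).loc[0, "q"]
    per = participant_acceptance(table)
    assert pooled != pytest.approx(per.q.mean())


def test_moving_average_window_arithmetic():
    # constant 60% acceptance at every index stays 0.6 after windowing
    rows = []
    for pid in range(1, 6):
        rows += _trial_rows(pid, ("a" if pid <= 3 else "r") * 9)
    ma = moving_average_acceptance(pd.DataFrame(rows), k=2)
    assert np.allclose(ma.q, 0.6)
    # hand-computed window: N=(1,2,3,2,1), M=(2,4,4,4,2) -> 9/16 at the center
    rows = []
    per_trial = [(1, 2), (2, 4), (3, 4), (2, 4), (1, 2)]
    pid = 0
    for n_participants in [4]:
        for pid in range(1, n_participants + 1):
            choices = ""
            for t, (N, M) in enumerate(per_trial):
                if pid <= M:
                    choices += "a" if pid <= N else "r"
                else:
                    choices += "m"
            rows += _trial_rows(pid, choices)
    ma = moving_average_acceptance(pd.DataFrame(rows), k=2)
    assert len(ma) == 1 and ma.iloc[0].trial_index == 3
    assert ma.iloc[0].q == pytest.approx(9 / 16)


def test_moving_average_k0_reduces_to_per_trial_proportion(small_kept):
    kept, _ = small_kept
    ma = moving_average_acceptance(kept, k=0)
    sub = kept[kept.analyzed & (kept.choice != "missing")]
    for group, g in sub.groupby("group"):
        direct = g.groupby("trial_index").apply(
            lambda x: (x.choice == "accept").mean(), include_groups=False
        )
        series = ma[ma.group == group].set_index("trial_index").q
        assert np.allclose(series, direct.loc[series.index])


def test_acceptance_curve_fit_recovers_slope_sign(rng):
    # monotone synthetic data: acceptance rises with magnitude
    rows = []
    pid = 0
    for rep in range(30):
        pid += 1
        choices, probs = "", []
        mags = list(range(15, 70, 5))
        for m in mags:
            p_acc = 1 / (1 + np.exp(-(m - 35) * 0.15))
            choices += "a" if rng.random() < p_acc else "r"
            probs.append(0.5)
        rows += _trial_rows(pid, choices, probs=probs)
    table = pd.DataFrame(rows)
    table["magnitude"] = np.tile(np.arange(15, 70, 5), pid)
    fit = rs.fit_acceptance_curve(table, on="magnitude")
    assert fit.converged and not fit.separation_flag
    assert 0.05 < fit.slope < 0.4
    # flat 50% data: slope near zero
    rows = []
    for pid in range(1, 31):
        choices = "".join("a" if rng.random() < 0.5 else "r" for _ in range(11))
        rows += _trial_rows(pid, choices)
    table = pd.DataFrame(rows)
    table["magnitude"] = np.tile(np.arange(15, 70, 5), 30)
    fit = rs.fit_acceptance_curve(table, on="magnitude")
    assert abs(fit.slope) < 0.03
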