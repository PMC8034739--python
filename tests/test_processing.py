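"""Epoch processing: intensity cut-points, non-wear detection, breaks,
day summaries and eligibility rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedpattern import (
    EpochSeries,
    ProcessingError,
    assess_eligibility,
    classify_intensity,
    count_breaks,
    detect_nonwear,
    summarize_day,
    summarize_participant,
)
from conftest import day_row, metrics_frame


# ---------------------------------------------------------------------------
# intensity cut-points
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "mets, expected",
    [
        (1.5, "SB"),  # sedentary boundary is inclusive
        (1.0, "SB"),
        (0.0, "SB"),
        (1.51, "LIPA"),
        (2.99, "LIPA"),
        (3.0, "MVPA"),  # MVPA boundary is inclusive
        (6.0, "MVPA"),
    ],
)
def test_intensity_cut_points(mets, expected):
    assert classify_intensity(mets) == expected


def test_negative_mets_rejected():
    with pytest.raises(ProcessingError):
        classify_intensity(-0.1)


# ---------------------------------------------------------------------------
# non-wear detection
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "mets, expected_nonwear",
    [
        (np.full(70, 0.9), 70),  # a full low run >= 60 is all non-wear
        (np.r_[[2.0], np.full(59, 0.9), [2.0]], 0),  # 59 < threshold
        # two allowance epochs inside: one 62-epoch interval
        (np.r_[np.full(30, 0.9), [1.0, 1.0], np.full(30, 0.9)], 62),
        # three allowance epochs: no qualifying window
        (np.r_[np.full(30, 0.9), [1.0, 1.0, 1.0], np.full(30, 0.9)], 0),
        # an epoch > 1.0 always terminates the window
        (np.r_[np.full(59, 0.5), [1.1], np.full(59, 0.5)], 0),
    ],
)
def test_nonwear_rule_examples(mets, expected_nonwear):
    assert detect_nonwear(np.asarray(mets)).sum() == expected_nonwear


def test_nonwear_marked_runs_are_maximal_and_long():
    rng = np.random.default_rng(5)
    mets = rng.choice([0.5, 0.95, 1.0, 2.0], size=2000, p=[0.7, 0.05, 0.05, 0.2])
    mask = detect_nonwear(mets)
    # every maximal marked run has length >= 60
    padded = np.r_[False, mask, False]
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    assert all(e - s >= 60 for s, e in zip(starts, ends))


def _nonwear_oracle_all_windows(mets):
    """Exhaustive enumeration of every qualifying window (any length)."""
    n = len(mets)
    bad = np.r_[0, np.cumsum(mets > 1.0)]
    tol = np.r_[0, np.cumsum((mets > 0.9) & (mets <= 1.0))]
    mask = np.zeros(n, bool)
    for a in range(n - 59):
        for b in range(a + 59, n):
            if bad[b + 1] - bad[a] > 0:
                break
            if tol[b + 1] - tol[a] <= 2:
                mask[a: b + 1] = True
    return mask


@settings(max_examples=250, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sampled_from([0.5, 0.9, 0.95, 1.0, 1.05, 2.0]), min_size=0, max_size=150
    )
)
def test_nonwear_matches_window_enumeration(values):
    mets = np.asarray(values)
    assert np.array_equal(detect_nonwear(mets), _nonwear_oracle_all_windows(mets))


def test_nonwear_monotone_under_lowering():
    # lowering any epoch to <= 0.9 METs never decreases non-wear minutes
    rng = np.random.default_rng(17)
    for _ in range(50):
        mets = rng.choice([0.5, 0.95, 1.0, 1.5], size=300, p=[0.55, 0.15, 0.15, 0.15])
        base = detect_nonwear(mets).sum()
        i = rng.integers(0, 300)
        lowered = mets.copy()
        lowered[i] = 0.5
        assert detect_nonwear(lowered).sum() >= base


# ---------------------------------------------------------------------------
# breaks
# ---------------------------------------------------------------------------


def test_break_counting_follows_definition():
    wear = np.ones(5, bool)
    assert count_breaks(np.array([1, 1, 0, 1, 0], bool), wear) == 2
    assert count_breaks(np.array([1, 1, 1, 1, 1], bool), wear) == 0
    # a non-wear boundary is not a break
    sb = np.array([1, 1, 0, 1, 1], bool)
    wear = np.array([1, 1, 0, 1, 1], bool)
    assert count_breaks(sb, wear) == 0


def test_breaks_bounded_by_sedentary_runs():
    rng = np.random.default_rng(3)
    for _ in range(100):
        sb = rng.random(200) < 0.6
        wear = rng.random(200) < 0.9
        runs = np.sum((sb & wear)[:-1] & ~(sb & wear)[1:]) + int((sb & wear)[-1])
        assert count_breaks(sb, wear) <= runs


# ---------------------------------------------------------------------------
# day summaries
# ---------------------------------------------------------------------------


def _day_series(mets_by_minute):
    ts = pd.date_range("2024-01-01", periods=1440, freq="min")
    return EpochSeries("P1", ts, mets_by_minute)


def _const_day(wear_minutes, level=1.2):
    """Wear at `level` METs for wear_minutes starting 06:00, device off
    elsewhere."""
    mets = np.full(1440, 0.5)
    mets[360: 360 + wear_minutes] = level
    return _day_series(mets)


@pytest.mark.parametrize("wear, valid", [(600, True), (599, False)])
def test_ten_hour_wear_rule_boundary(wear, valid):
    s = _const_day(wear)
    row = summarize_day(s, detect_nonwear(s), "2024-01-01", "workday")
    assert row["wear_min_whole"] == wear
    assert row["valid_day"] is valid or row["valid_day"] == valid


@pytest.mark.parametrize("morning_wear, period_valid", [(90, True), (89, False)])
def test_period_wear_rule_boundary(morning_wear, period_valid):
    mets = np.full(1440, 0.5)
    mets[360: 360 + morning_wear] = 1.2  # morning wear block
    mets[720:1440] = 1.2  # afternoon + evening fully worn
    s = _day_series(mets)
    row = summarize_day(s, detect_nonwear(s), "2024-01-01", "workday")
    assert row["wear_min_morning"] == morning_wear
    assert row["valid_day"]
    assert bool(row["period_valid"]) == period_valid


def test_fully_sedentary_day():
    mets = np.full(1440, 0.5)
    mets[360:1440] = 1.2
    s = _day_series(mets)
    row = summarize_day(s, detect_nonwear(s), "2024-01-01", "workday")
    for scope in ("whole", "morning", "afternoon", "evening"):
        assert row[f"sb_pct_{scope}"] == 100.0
        assert row[f"breaks_{scope}"] == 0
    assert row["wear_min_whole"] == 1080


def test_zero_wear_scope_is_missing_not_zero():
    s = _const_day(600)  # wear 06:00-16:00; evening fully off
    row = summarize_day(s, detect_nonwear(s), "2024-01-01", "workday")
    assert row["wear_min_evening"] == 0
    assert np.isnan(row["sb_pct_evening"])


def test_minutes_conserve_across_intensities_and_periods(small_day_metrics):
    df = small_day_metrics
    for scope in ("whole", "morning", "afternoon", "evening"):
        total = df[f"sb_min_{scope}"] + df[f"lipa_min_{scope}"] + df[f"mvpa_min_{scope}"]
        assert (total == df[f"wear_min_{scope}"]).all()
    for m in ("wear_min", "sb_min", "lipa_min", "mvpa_min"):
        period_sum = df[[f"{m}_morning", f"{m}_afternoon", f"{m}_evening"]].sum(axis=1)
        assert (period_sum == df[f"{m}_whole"]).all()


def test_missing_diary_date_is_an_error():
    s = _const_day(700)
    diary = pd.DataFrame(
        {"participant_id": ["P1"], "date": ["2024-01-02"], "day_type": ["workday"]}
    )
    with pytest.raises(ProcessingError, match="P1.*2024-01-01"):
        summarize_participant(s, diary)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


def test_minimal_qualifying_pattern_is_eligible():
    rows = [day_row(date=f"2024-01-0{i}", day_type="workday") for i in range(1, 4)]
    rows.append(day_row(date="2024-01-06", day_type="non_workday"))
    ok, reasons = assess_eligibility(metrics_frame(rows))
    assert ok and not reasons


def test_no_valid_nonworkday_is_ineligible():
    rows = [day_row(date=f"2024-01-0{i}", day_type="workday") for i in range(1, 5)]
    ok, reasons = assess_eligibility(metrics_frame(rows))
    assert not ok
    assert any("non-workday" in r for r in reasons)


def test_all_invalid_days_fail_every_criterion():
    rows = [
        day_row(date=f"2024-01-0{i}", day_type=t, valid=False)
        for i, t in enumerate(["workday"] * 3 + ["non_workday"], start=1)
    ]
    ok, reasons = assess_eligibility(metrics_frame(rows))
    assert not ok
    assert len(reasons) == 5
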