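"""Minute-epoch accelerometer processing.

Implements the study's processing rules: METs intensity cut-points
(sedentary <=1.5, light >1.5 to <3.0, MVPA >=3.0), non-wear detection
(>=60 consecutive minutes at <=0.9 METs with an allowance of up to two
minutes at <=1.0 METs inside the window), metric computation restricted
to 06:00-24:00 with morning/afternoon/evening periods of six hours each,
sedentary-break counting, and the wear-validity / eligibility rules
(valid day >=10 h wear; period validity >=90 min wear per period;
eligible participants need >=4 valid days with >=3 valid workdays and
>=1 valid non-workday, period-valid likewise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProcessingError",
    "EpochSeries",
    "SCOPES",
    "classify_intensity",
    "classify_intensity_codes",
    "detect_nonwear",
    "count_breaks",
    "summarize_day",
    "summarize_participant",
    "process_cohort",
    "assess_eligibility",
    "eligibility_table",
]

SB, LIPA, MVPA = 0, 1, 2
INTENSITY_NAMES = {SB: "SB", LIPA: "LIPA", MVPA: "MVPA"}

#: metric scopes: half-open minute-of-day windows
SCOPES = {
    "whole": (360, 1440),
    "morning": (360, 720),
    "afternoon": (720, 1080),
    "evening": (1080, 1440),
}

MIN_NONWEAR_RUN = 60  # epochs
NONWEAR_CEILING = 0.9  # METs treated as "no activity"
ALLOWANCE_CEILING = 1.0  # limited-movement allowance upper bound
ALLOWANCE_COUNT = 2  # tolerated epochs per window
VALID_DAY_WEAR_MIN = 600  # 10 h
PERIOD_VALID_WEAR_MIN = 90  # 25% of a 6-h period


class ProcessingError(ValueError):
    """Raised on malformed epoch input."""


@dataclass
class EpochSeries:
    """One participant's minute-resolution METs stream."""

    participant_id: str
    timestamps: pd.DatetimeIndex
    mets: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.mets = np.asarray(self.mets, dtype=float)
        if len(self.timestamps) != len(self.mets):
            raise ProcessingError(
                f"{self.participant_id}: {len(self.timestamps)} timestamps vs "
                f"{len(self.mets)} METs values"
            )
        if len(self.mets) and np.nanmin(self.mets) < 0:
            raise ProcessingError(f"{self.participant_id}: negative METs value")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            if (deltas <= 0).any():
                raise ProcessingError(
                    f"{self.participant_id}: timestamps not strictly increasing"
                )
            same_day = self.timestamps.normalize()[1:] == self.timestamps.normalize()[:-1]
            bad = same_day & (deltas != 60_000_000_000)
            if bad.any():
                first = self.timestamps[1:][bad][0]
                raise ProcessingError(
                    f"{self.participant_id}: non 1-minute spacing before {first}"
                )

    def __len__(self) -> int:
        return len(self.mets)


# ---------------------------------------------------------------------------
# intensity classification
# ---------------------------------------------------------------------------


def classify_intensity(mets: float) -> str:
    """Classify a single wear epoch: 'SB' (<=1.5 METs), 'LIPA'
    (>1.5 to <3.0) or 'MVPA' (>=3.0)."""
    if mets < 0:
        raise ProcessingError(f"negative METs value: {mets}")
    if mets <= 1.5:
        return "SB"
    if mets < 3.0:
        return "LIPA"
    return "MVPA"


def classify_intensity_codes(mets: np.ndarray) -> np.ndarray:
    """Vectorized intensity codes (0=SB, 1=LIPA, 2=MVPA)."""
    mets = np.asarray(mets, dtype=float)
    if len(mets) and np.nanmin(mets) < 0:
        raise ProcessingError("negative METs value")
    return np.where(mets <= 1.5, SB, np.where(mets < 3.0, LIPA, MVPA))


# ---------------------------------------------------------------------------
# non-wear detection
# ---------------------------------------------------------------------------


def detect_nonwear(series) -> np.ndarray:
    """Boolean non-wear mask (True = device off).

    An epoch is non-wear iff it lies inside some window of >=60
    consecutive epochs in which every epoch is <=1.0 METs, at most two
    epochs exceed 0.9 METs (the limited-movement allowance), and that is
    therefore never interrupted by an epoch >1.0 METs.  Marking the union
    of all such windows makes every marked maximal run >=60 epochs and
    extends windows greedily to maximal length; tolerated allowance
    epochs are inside the marked interval.
    """
    mets = series.mets if isinstance(series, EpochSeries) else np.asarray(series, float)
    n = len(mets)
    mask = np.zeros(n, dtype=bool)
    if n < MIN_NONWEAR_RUN:
        return mask

    low = mets <= ALLOWANCE_CEILING  # candidate epochs
    tol = low & (mets > NONWEAR_CEILING)  # allowance epochs

    # scan maximal runs of candidate epochs; inside a run, slide a window
    # keeping at most ALLOWANCE_COUNT allowance epochs
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < n and low[j]:
            j += 1
        run_tol = np.flatnonzero(tol[i:j]) + i  # allowance positions in run
        # for each window start a, the window may extend to just before the
        # (ALLOWANCE_COUNT+1)-th allowance epoch at or after a
        ptr = 0
        marked_to = i  # first unmarked position
        for a in range(i, j - MIN_NONWEAR_RUN + 1):
            while ptr < len(run_tol) and run_tol[ptr] < a:
                ptr += 1
            if ptr + ALLOWANCE_COUNT < len(run_tol):
                b = run_tol[ptr + ALLOWANCE_COUNT] - 1
            else:
                b = j - 1
            if b - a + 1 >= MIN_NONWEAR_RUN:
                mask[max(a, marked_to): b + 1] = True
                marked_to = b + 1
        i = j
    return mask


# ---------------------------------------------------------------------------
# breaks
# ---------------------------------------------------------------------------


def count_breaks(sb: np.ndarray, wear: np.ndarray, scope: np.ndarray | None = None) -> int:
    """Count sedentary breaks: wear SB epoch immediately followed by a
    wear non-SB epoch.  Transitions into non-wear do not count.  If
    *scope* (boolean mask) is given, only transitions whose non-SB epoch
    lies in scope are counted."""
    sb = np.asarray(sb, bool)
    wear = np.asarray(wear, bool)
    if len(sb) < 2:
        return 0
    trans = wear[:-1] & wear[1:] & sb[:-1] & ~sb[1:]
    if scope is not None:
        trans = trans & np.asarray(scope, bool)[1:]
    return int(trans.sum())


# ---------------------------------------------------------------------------
# per-day summaries
# ---------------------------------------------------------------------------


def summarize_day(
    series: EpochSeries,
    mask: np.ndarray,
    date,
    day_type: str,
) -> dict:
    """Compute :class:`DayMetrics`-style quantities for one calendar date.

    All metrics are restricted to wear epochs within 06:00-24:00; the
    three periods are [06:00, 12:00), [12:00, 18:00) and [18:00, 24:00),
    each epoch assigned by its start timestamp.  Percentage metrics are
    NaN (not 0) where a scope has no wear; the break rate is NaN where a
    scope has no sedentary time.
    """
    date = pd.Timestamp(date)
    in_day = series.timestamps.normalize() == date
    ts = series.timestamps[in_day]
    mets = series.mets[in_day]
    wear = ~np.asarray(mask, bool)[in_day]
    mod = ts.hour.values * 60 + ts.minute.values  # minute of day
    codes = classify_intensity_codes(mets)
    sb = codes == SB

    row: dict = {
        "participant_id": series.participant_id,
        "date": date.date().isoformat(),
        "day_type": day_type,
    }
    for scope, (lo, hi) in SCOPES.items():
        sel = (mod >= lo) & (mod < hi)
        w = sel & wear
        wear_min = int(w.sum())
        sb_min = int((w & sb).sum())
        lipa_min = int((w & (codes == LIPA)).sum())
        mvpa_min = int((w & (codes == MVPA)).sum())
        breaks = count_breaks(sb, wear, scope=sel)
        row[f"wear_min_{scope}"] = wear_min
        row[f"sb_min_{scope}"] = sb_min
        row[f"lipa_min_{scope}"] = lipa_min
        row[f"mvpa_min_{scope}"] = mvpa_min
        for name, mins in (("sb", sb_min), ("lipa", lipa_min), ("mvpa", mvpa_min)):
            row[f"{name}_pct_{scope}"] = (
                100.0 * mins / wear_min if wear_min > 0 else np.nan
            )
        row[f"breaks_{scope}"] = breaks
        row[f"breaks_per_sed_hour_{scope}"] = (
            breaks / (sb_min / 60.0) if sb_min > 0 else np.nan
        )
    row["valid_day"] = row["wear_min_whole"] >= VALID_DAY_WEAR_MIN
    row["period_valid"] = bool(
        row["valid_day"]
        and all(row[f"wear_min_{p}"] >= PERIOD_VALID_WEAR_MIN for p in
                ("morning", "afternoon", "evening"))
    )
    return row


def summarize_participant(series: EpochSeries, diary: pd.DataFrame) -> pd.DataFrame:
    """Per-day metrics for every date present in one participant's series.

    The diary must label each date; a missing diary entry is an error
    naming the participant and date.
    """
    dmap = {
        pd.Timestamp(d).normalize(): t
        for d, t in zip(diary["date"], diary["day_type"])
    }
    mask = detect_nonwear(series)
    rows = []
    for date in sorted(set(series.timestamps.normalize())):
        if date not in dmap:
            raise ProcessingError(
                f"diary entry missing for participant "
                f"{series.participant_id}, date {date.date()}"
            )
        rows.append(summarize_day(series, mask, date, dmap[date]))
    return pd.DataFrame(rows)


def process_cohort(series_map: dict, diary: pd.DataFrame) -> pd.DataFrame:
    """Day metrics for a whole cohort (one row per participant-date)."""
    frames = []
    for pid in sorted(series_map):
        sub = diary[diary["participant_id"] == pid]
        frames.append(summarize_participant(series_map[pid], sub))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


def assess_eligibility(day_metrics: pd.DataFrame) -> tuple[bool, list[str]]:
    """Apply the participant-inclusion rules to one participant's days.

    Eligible iff: >=4 valid days, >=3 valid workdays, >=1 valid
    non-workday, and the same workday/non-workday minima among
    period-valid days.  Returns ``(eligible, reasons)`` with one reason
    per failed criterion.
    """
    if day_metrics.empty:
        raise ProcessingError("no days present")
    valid = day_metrics[day_metrics["valid_day"].astype(bool)]
    pvalid = day_metrics[day_metrics["period_valid"].astype(bool)]
    reasons = []
    if len(valid) < 4:
        reasons.append(f"only {len(valid)} valid days (need >= 4)")
    if (valid["day_type"] == "workday").sum() < 3:
        reasons.append("fewer than 3 valid workdays")
    if (valid["day_type"] == "non_workday").sum() < 1:
        reasons.append("no valid non-workday")
    if (pvalid["day_type"] == "workday").sum() < 3:
        reasons.append("fewer than 3 period-valid workdays")
    if (pvalid["day_type"] == "non_workday").sum() < 1:
        reasons.append("no period-valid non-workday")
    return (not reasons), reasons


def eligibility_table(day_metrics: pd.DataFrame) -> pd.DataFrame:
    """Eligibility report: one row per participant with reasons."""
    rows = []
    for pid, sub in day_metrics.groupby("participant_id", sort=True):
        ok, reasons = assess_eligibility(sub)
        rows.append(
            {"participant_id": pid, "eligible": ok, "reasons": "; ".join(reasons)}
        )
    return pd.DataFrame(rows)
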