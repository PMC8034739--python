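"""Day-type aggregation and diurnal variation-level features.

The clustering feature of a period is its *variation level*:
100 x (period sedentary % of wear) / (whole-day sedentary % of wear),
computed separately for workdays and non-workdays, giving six features
per participant (morning/afternoon/evening x day type).

Two aggregation conventions are available.  Under the default
``"pooled"`` convention, minutes are summed across a participant's
contributing days before any ratio is taken; this makes the
wear-weighted mean of the three variation levels within a day type
exactly 100.  The ``"daily_mean"`` alternative averages per-day ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic import DAY_TYPES, FEATURE_COLUMNS, PERIODS

__all__ = [
    "FeatureError",
    "pool_daytype_metrics",
    "variation_level",
    "compute_variation_features",
    "build_feature_matrix",
    "daytype_summary_table",
]

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    """A variation-level feature is undefined for a participant."""


def pool_daytype_metrics(
    day_metrics: pd.DataFrame, day_type: str, convention: str = "pooled"
) -> dict:
    """Aggregate one participant's valid days of one type.

    Whole-day quantities pool across valid days; period quantities pool
    across period-valid days only.  Percentages are ratios of pooled
    minutes (or, under ``"daily_mean"``, means of per-day percentages).
    """
    valid = day_metrics[
        (day_metrics["day_type"] == day_type) & day_metrics["valid_day"].astype(bool)
    ]
    pvalid = day_metrics[
        (day_metrics["day_type"] == day_type) & day_metrics["period_valid"].astype(bool)
    ]
    if valid.empty:
        raise FeatureError(f"no valid {day_type} days")

    out = {"day_type": day_type, "n_days_pooled": len(valid),
           "n_period_days_pooled": len(pvalid)}
    for scope in ("whole", "morning", "afternoon", "evening"):
        sub = valid if scope == "whole" else pvalid
        if sub.empty:
            for m in ("wear_min", "sb_min", "sb_pct", "lipa_pct", "mvpa_pct",
                      "breaks_per_sed_hour"):
                out[f"{m}_{scope}"] = np.nan
            continue
        wear = sub[f"wear_min_{scope}"].sum()
        sbm = sub[f"sb_min_{scope}"].sum()
        out[f"wear_min_{scope}"] = float(wear)
        out[f"sb_min_{scope}"] = float(sbm)
        if convention == "pooled":
            for name in ("sb", "lipa", "mvpa"):
                mins = sub[f"{name}_min_{scope}"].sum()
                out[f"{name}_pct_{scope}"] = (
                    100.0 * mins / wear if wear > 0 else np.nan
                )
            out[f"breaks_per_sed_hour_{scope}"] = (
                sub[f"breaks_{scope}"].sum() / (sbm / 60.0) if sbm > 0 else np.nan
            )
        elif convention == "daily_mean":
            for name in ("sb", "lipa", "mvpa"):
                out[f"{name}_pct_{scope}"] = float(sub[f"{name}_pct_{scope}"].mean())
            out[f"breaks_per_sed_hour_{scope}"] = float(
                sub[f"breaks_per_sed_hour_{scope}"].mean()
            )
        else:
            raise ValueError(f"unknown convention {convention!r}")
    return out


def variation_level(sb_pct_period: float, sb_pct_day: float) -> float:
    """100 x period sedentary percentage / whole-day sedentary percentage."""
    if not sb_pct_day > 0:
        raise FeatureError("whole-day sedentary percentage is zero; feature undefined")
    return 100.0 * sb_pct_period / sb_pct_day


def compute_variation_features(
    day_metrics: pd.DataFrame, convention: str = "pooled"
) -> np.ndarray:
    """Six variation levels for one participant, ordered as
    :data:`~sedpattern.synthetic.FEATURE_COLUMNS`.

    Under the pooled convention the whole-day denominator is pooled over
    the same period-valid days as the period numerators, so the
    wear-weighted mean of the three features within a day type is
    exactly 100.
    """
    feats = []
    for dt in DAY_TYPES:
        pvalid = day_metrics[
            (day_metrics["day_type"] == dt) & day_metrics["period_valid"].astype(bool)
        ]
        if pvalid.empty:
            raise FeatureError(f"no period-valid {dt} days")
        if convention == "pooled":
            wear_p = np.array([pvalid[f"wear_min_{p}"].sum() for p in PERIODS], float)
            sb_p = np.array([pvalid[f"sb_min_{p}"].sum() for p in PERIODS], float)
            if (wear_p <= 0).any():
                raise FeatureError(f"a {dt} period has zero pooled wear")
            day_pct = 100.0 * sb_p.sum() / wear_p.sum()
            feats.extend(
                variation_level(100.0 * sb_p[i] / wear_p[i], day_pct)
                for i in range(3)
            )
        elif convention == "daily_mean":
            per_day = []
            for _, day in pvalid.iterrows():
                if not day["sb_pct_whole"] > 0:
                    raise FeatureError("whole-day sedentary percentage is zero")
                per_day.append(
                    [variation_level(day[f"sb_pct_{p}"], day["sb_pct_whole"])
                     for p in PERIODS]
                )
            feats.extend(np.mean(per_day, axis=0))
        else:
            raise ValueError(f"unknown convention {convention!r}")
    return np.asarray(feats)


def build_feature_matrix(
    day_metrics: pd.DataFrame,
    participants=None,
    convention: str = "pooled",
) -> tuple[pd.DataFrame, list[str]]:
    """Feature matrix for eligible participants.

    Rows are ordered by sorted participant_id; columns follow
    :data:`~sedpattern.synthetic.FEATURE_COLUMNS`.  Participants with any
    undefined feature are dropped and reported in the second return
    value (also logged).
    """
    if participants is None:
        participants = sorted(day_metrics["participant_id"].unique())
    rows, idx, dropped = [], [], []
    for pid in sorted(participants):
        sub = day_metrics[day_metrics["participant_id"] == pid]
        try:
            rows.append(compute_variation_features(sub, convention=convention))
            idx.append(pid)
        except FeatureError as exc:
            dropped.append(pid)
            logger.warning("participant %s dropped: %s", pid, exc)
    if dropped:
        logger.info("%d participants dropped with undefined features", len(dropped))
    mat = pd.DataFrame(
        np.asarray(rows).reshape(len(rows), 6) if rows else np.empty((0, 6)),
        index=pd.Index(idx, name="participant_id"),
        columns=list(FEATURE_COLUMNS),
    )
    return mat, dropped


def daytype_summary_table(
    day_metrics: pd.DataFrame, participants=None, convention: str = "pooled"
) -> pd.DataFrame:
    """Per-participant day-type summaries (workday / non-workday /
    overall rows) for cluster profiling.

    "overall" pools across all valid days regardless of day type.
    """
    if participants is None:
        participants = sorted(day_metrics["participant_id"].unique())
    rows = []
    for pid in sorted(participants):
        sub = day_metrics[day_metrics["participant_id"] == pid]
        for dt in DAY_TYPES:
            try:
                rec = pool_daytype_metrics(sub, dt, convention=convention)
            except FeatureError:
                continue
            rec["participant_id"] = pid
            rows.append(rec)
        overall = sub.copy()
        overall["day_type"] = "overall"
        try:
            rec = pool_daytype_metrics(overall, "overall", convention=convention)
            rec["participant_id"] = pid
            rows.append(rec)
        except FeatureError:
            pass
    return pd.DataFrame(rows)
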