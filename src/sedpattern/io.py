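"""File I/O, pipeline configuration and the end-to-end driver.

CSV interchange formats (UTF-8, comma-separated, header row required):

* epoch CSV — ``participant_id, timestamp, mets`` with ISO-8601
  minute-resolution timestamps (epoch start) and float METs;
* diary CSV — ``participant_id, date, day_type`` with day_type in
  {workday, non_workday};
* covariate / domain CSVs — ``participant_id`` plus arbitrary columns.

:func:`run_pipeline` chains reading, non-wear detection, day metrics,
eligibility, variation-level features, two-step clustering and cluster
profiling, writing each stage's output plus a run manifest whose
exclusion counts telescope (n_input - sum of exclusions = n_analyzed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import kmeans_refine, select_k, ward_linkage
from .features import build_feature_matrix, daytype_summary_table
from .processing import EpochSeries, ProcessingError, eligibility_table, process_cohort
from .profiling import build_profile_tables
from .synthetic import RecruitmentBundle

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_epoch_csv",
    "read_diary_csv",
    "write_epoch_csv",
    "write_diary_csv",
    "run_pipeline",
    "apply_exclusion_flow",
]

logger = logging.getLogger(__name__)

CLUSTER_LABELS = {
    0: "stable_sedentary",
    1: "off_morning_break",
    2: "off_afternoon_break",
    3: "evening_sedentary",
}


class PipelineError(RuntimeError):
    """The pipeline cannot proceed (e.g. no eligible participants)."""


@dataclass
class PipelineConfig:
    """Paths and options driving :func:`run_pipeline`."""

    epoch_csv: str
    diary_csv: str
    output_dir: str
    covariates_csv: str | None = None
    domain_csv: str | None = None
    pooling: str = "pooled"  # or "daily_mean"
    k: int | None = None  # fixed cluster count; None -> select from dendrogram
    k_min: int = 2
    k_max: int = 8
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError(f"invalid k range [{self.k_min}, {self.k_max}]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_epoch_csv(path) -> dict[str, EpochSeries]:
    """Read an epoch CSV into per-participant series sorted by timestamp.

    Duplicate (participant, timestamp) pairs and within-day minute gaps
    are errors naming the first offender; an empty file yields an empty
    map with a warning.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "timestamp", "mets"}
    missing = required - set(df.columns)
    if missing:
        raise ProcessingError(f"epoch CSV missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"epoch CSV {path} is empty", stacklevel=2)
        return {}
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise ProcessingError(f"unparseable timestamp in {path}: {exc}") from exc
    if (df["mets"] < 0).any():
        bad = df.loc[df["mets"] < 0].iloc[0]
        raise ProcessingError(
            f"negative METs for {bad['participant_id']} at {bad['timestamp']}"
        )
    out: dict[str, EpochSeries] = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        sub = sub.sort_values("timestamp")
        dup = sub["timestamp"].duplicated()
        if dup.any():
            t = sub.loc[dup, "timestamp"].iloc[0]
            raise ProcessingError(f"duplicate epoch for {pid} at {t}")
        ts = pd.DatetimeIndex(sub["timestamp"])
        same_day = ts.normalize()[1:] == ts.normalize()[:-1]
        gaps = same_day & (np.diff(ts.asi8) != 60_000_000_000)
        if gaps.any():
            t = ts[1:][gaps][0]
            raise ProcessingError(f"minute gap within a day for {pid} before {t}")
        out[str(pid)] = EpochSeries(
            participant_id=str(pid), timestamps=ts, mets=sub["mets"].to_numpy()
        )
    return out


def read_diary_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "date", "day_type"}
    missing = required - set(df.columns)
    if missing:
        raise ProcessingError(f"diary CSV missing columns: {sorted(missing)}")
    bad = set(df["day_type"].unique()) - {"workday", "non_workday"}
    if bad:
        raise ProcessingError(f"unknown day_type values: {sorted(bad)}")
    return df


def write_epoch_csv(series_map: dict[str, EpochSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M"),
                "mets": np.round(s.mets, 4),
            }
        )
        for _, s in sorted(series_map.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_diary_csv(diary: pd.DataFrame, path) -> None:
    diary.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# exclusion flow (recruitment-style filter chain)
# ---------------------------------------------------------------------------


def apply_exclusion_flow(bundle: RecruitmentBundle) -> dict:
    """Apply the study's exclusion filters to a recruitment bundle.

    Order: insufficient accelerometer data (eligibility rules on the
    day records) -> missing work-domain self-report -> missing
    sociodemographic covariates.  Returns a manifest whose counts
    telescope to the number analyzed.
    """
    elig = eligibility_table(bundle.day_records)
    eligible = set(elig.loc[elig["eligible"], "participant_id"])
    all_ids = list(elig["participant_id"])
    n_input = len(all_ids)
    excluded_wear = [p for p in all_ids if p not in eligible]

    work = bundle.work_sb.set_index("participant_id")["work_sb_min"]
    remaining = [p for p in all_ids if p in eligible]
    excluded_work = [p for p in remaining if pd.isna(work.get(p))]
    remaining = [p for p in remaining if p not in set(excluded_work)]

    cov = bundle.covariates.set_index("participant_id")
    excluded_cov = [p for p in remaining if cov.loc[p].isna().any()]
    analyzed = [p for p in remaining if p not in set(excluded_cov)]

    return {
        "n_input": n_input,
        "n_excluded_insufficient_accelerometer": len(excluded_wear),
        "n_excluded_missing_work_sb": len(excluded_work),
        "n_excluded_missing_covariates": len(excluded_cov),
        "n_analyzed": len(analyzed),
        "analyzed_ids": analyzed,
    }


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain and write all stage outputs.

    Returns the run manifest (also written as ``manifest.json``).  The
    run is deterministic given identical inputs and configuration: the
    only randomness in the package lives in the synthetic generators.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    series_map = read_epoch_csv(config.epoch_csv)
    diary = read_diary_csv(config.diary_csv)
    n_input = len(series_map)

    day_metrics = process_cohort(series_map, diary)
    day_metrics.to_csv(out / "day_metrics.csv", index=False)

    elig = eligibility_table(day_metrics)
    elig.to_csv(out / "eligibility.csv", index=False)
    eligible_ids = sorted(elig.loc[elig["eligible"], "participant_id"])
    n_excl_wear = n_input - len(eligible_ids)

    remaining = eligible_ids
    n_excl_work = n_excl_cov = 0
    covariates = domain = None
    if config.domain_csv:
        domain = pd.read_csv(config.domain_csv).set_index("participant_id")
        if "work_sb_min" in domain.columns:
            keep = [p for p in remaining
                    if p in domain.index and not pd.isna(domain.loc[p, "work_sb_min"])]
            n_excl_work = len(remaining) - len(keep)
            remaining = keep
    if config.covariates_csv:
        covariates = pd.read_csv(config.covariates_csv).set_index("participant_id")
        keep = [p for p in remaining
                if p in covariates.index and not covariates.loc[p].isna().any()]
        n_excl_cov = len(remaining) - len(keep)
        remaining = keep

    if not remaining:
        raise PipelineError(
            f"zero eligible participants (input {n_input}, "
            f"excluded wear {n_excl_wear}, work-SB {n_excl_work}, "
            f"covariates {n_excl_cov})"
        )

    features, dropped = build_feature_matrix(
        day_metrics, participants=remaining, convention=config.pooling
    )
    features.to_csv(out / "features.csv")

    tree = ward_linkage(features.to_numpy())
    k = config.k if config.k is not None else select_k(tree, config.k_min, config.k_max)
    model = kmeans_refine(features.to_numpy(), tree, k)

    assignments = pd.Series(
        model.assignments, index=features.index, name="cluster_id"
    )
    assign_df = assignments.reset_index()
    assign_df["cluster_label"] = [
        CLUSTER_LABELS.get(c, f"cluster_{c}") if k == 4 else f"cluster_{c}"
        for c in assign_df["cluster_id"]
    ]
    assign_df.to_csv(out / "assignments.csv", index=False)
    pd.DataFrame(model.centroids, columns=features.columns).to_csv(
        out / "centroids.csv", index_label="cluster_id"
    )
    with open(out / "dendrogram.json", "w") as fh:
        json.dump(
            {
                "merges": tree.merges.tolist(),
                "heights": tree.heights.tolist(),
                "n_leaves": tree.n_leaves,
            },
            fh,
        )

    summaries = daytype_summary_table(
        day_metrics, participants=list(features.index), convention=config.pooling
    )
    tables = build_profile_tables(
        assignments,
        covariates=covariates.loc[covariates.index.intersection(features.index)]
        if covariates is not None else None,
        daytype_summaries=summaries,
        domain_sb=domain.loc[domain.index.intersection(features.index)]
        if domain is not None else None,
    )
    tables.characteristics.to_csv(out / "table_characteristics.csv", index=False)
    tables.behavior.to_csv(out / "table_behavior.csv", index=False)
    tables.domains.to_csv(out / "table_domains.csv", index=False)
    with open(out / "test_results.json", "w") as fh:
        json.dump(tables.results, fh, indent=1, default=float)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "n_input": n_input,
        "n_excluded_insufficient_accelerometer": n_excl_wear,
        "n_excluded_missing_work_sb": n_excl_work,
        "n_excluded_missing_covariates": n_excl_cov,
        "n_dropped_undefined_features": len(dropped),
        "n_analyzed": len(features),
        "k": int(k),
        "within_ss": model.within_ss,
        "cluster_sizes": np.bincount(model.assignments, minlength=k).tolist(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
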