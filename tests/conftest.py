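import numpy as np
import pandas as pd
import pytest

from sedpattern import (
    ArchetypeProfile,
    CohortConfig,
    study_archetypes,
)
from sedpattern.synthetic import DAY_TYPES, PERIODS


@pytest.fixture(scope="session")
def archetypes():
    return study_archetypes()


def make_flat_archetype(sb=0.6, sd=0.05, **kw):
    """Archetype with the same sedentary propensity in every period."""
    keys = [(d, p) for d in DAY_TYPES for p in PERIODS]
    return ArchetypeProfile(
        name=kw.pop("name", "flat"),
        sb_target={k: sb for k in keys},
        sb_sd={k: sd for k in keys},
        **kw,
    )


def make_separated_archetypes(sd=8.0, day_sb=60.0):
    """Four archetypes with well-separated variation-level profiles
    (pairwise mean separation >= 3 SD in feature space)."""
    patterns = [
        (130.0, 85.0, 85.0),
        (85.0, 130.0, 85.0),
        (85.0, 85.0, 130.0),
        (100.0, 100.0, 100.0),
    ]
    out = []
    for i, pat in enumerate(patterns):
        vmean = {}
        vsd = {}
        for d in DAY_TYPES:
            for p, v in zip(PERIODS, pat):
                vmean[(d, p)] = v
                vsd[(d, p)] = sd
        out.append(
            ArchetypeProfile.from_variation_profile(
                f"sep{i}", {d: day_sb for d in DAY_TYPES}, vmean, vsd
            )
        )
    return out


@pytest.fixture(scope="session")
def separated_archetypes():
    return make_separated_archetypes()


@pytest.fixture(scope="session")
def small_epoch_cohort(archetypes):
    """12 eligible-by-construction participants, mixed archetypes."""
    from sedpattern import generate_epoch_cohort

    config = CohortConfig(
        n_participants=12,
        mixture_weights=(0.5, 0.0, 0.0, 0.5),
        seed=42,
    )
    return generate_epoch_cohort(config, archetypes)


@pytest.fixture(scope="session")
def small_day_metrics(small_epoch_cohort):
    from sedpattern import process_cohort

    series_map, diary, _ = small_epoch_cohort
    return process_cohort(series_map, diary)


def day_row(pid="P1", date="2024-01-01", day_type="workday", valid=True,
            period_valid=None, **metrics):
    """Minimal hand-built day-metrics row for eligibility tests."""
    row = {
        "participant_id": pid,
        "date": date,
        "day_type": day_type,
        "valid_day": valid,
        "period_valid": valid if period_valid is None else period_valid,
    }
    row.update(metrics)
    return row


def metrics_frame(rows):
    return pd.DataFrame(rows)
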