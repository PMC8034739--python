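"""Synthetic cohorts with known diurnal sedentary-behavior cluster structure.

Two levels of realism are provided:

* :func:`generate_feature_cohort` draws the six variation-level features
  directly from a Gaussian mixture over behavioral archetypes — fast input
  for clustering experiments.
* :func:`generate_epoch_cohort` simulates minute-epoch METs streams
  (wake windows, device-off gaps, alternating sedentary/active bouts) so
  the full processing chain — non-wear detection, day validation, pooling,
  feature computation — can be exercised end to end.

Categorical covariate tables with cluster-linked distributions and a
recruitment fixture with engineered eligibility failures round out the
test bed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ArchetypeProfile",
    "CohortConfig",
    "RecruitmentFixtureConfig",
    "RecruitmentBundle",
    "study_archetypes",
    "STUDY_MIXTURE_WEIGHTS",
    "generate_feature_cohort",
    "generate_epoch_cohort",
    "generate_sociodemographic_table",
    "generate_recruitment_fixture",
    "study_covariate_specs",
    "DAY_TYPES",
    "PERIODS",
    "FEATURE_COLUMNS",
]

DAY_TYPES = ("workday", "non_workday")
PERIODS = ("morning", "afternoon", "evening")
#: Fixed feature order used everywhere downstream.
FEATURE_COLUMNS = tuple(f"{d}_{p}" for d in DAY_TYPES for p in PERIODS)

WAKE_DAY_START = 360  # 06:00, minutes of day; metrics window lower bound
DAY_END = 1440


class ConfigurationError(ValueError):
    """A generator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchetypeProfile:
    """One behavioral archetype: period-specific sedentary propensities.

    ``sb_target[(day_type, period)]`` is the target sedentary fraction of
    wear time in that clock period; ``sb_sd`` the between-person SD of
    that fraction.  Bout-length means (minutes) set the tempo of the
    sedentary/active alternation; ``mvpa_share`` is the fraction of
    non-sedentary wear time spent at >=3.0 METs.
    """

    name: str
    sb_target: dict
    sb_sd: dict
    mean_bout_sed: float = 7.0
    mean_bout_active: float = 4.0
    mvpa_share: float = 0.18

    def __post_init__(self) -> None:
        keys = {(d, p) for d in DAY_TYPES for p in PERIODS}
        if set(self.sb_target) != keys or set(self.sb_sd) != keys:
            raise ConfigurationError(
                f"archetype {self.name!r}: sb_target/sb_sd must cover all "
                f"day_type x period combinations"
            )
        for k, v in self.sb_target.items():
            if not 0.0 < v < 1.0:
                raise ConfigurationError(
                    f"archetype {self.name!r}: sb_target{k} = {v} outside (0, 1)"
                )
        if any(s <= 0 for s in self.sb_sd.values()):
            raise ConfigurationError(f"archetype {self.name!r}: sb_sd must be > 0")
        if self.mean_bout_sed < 1 or self.mean_bout_active < 1:
            raise ConfigurationError(
                f"archetype {self.name!r}: mean bout lengths must be >= 1 minute"
            )
        if not 0.0 <= self.mvpa_share <= 1.0:
            raise ConfigurationError(f"archetype {self.name!r}: mvpa_share outside [0, 1]")

    # -- derived variation-level profile ----------------------------------

    def day_sb(self, day_type: str) -> float:
        """Whole-day sedentary fraction implied by equal period wear."""
        return float(np.mean([self.sb_target[(day_type, p)] for p in PERIODS]))

    def variation_means(self) -> np.ndarray:
        """Implied variation-level means, ordered as :data:`FEATURE_COLUMNS`.

        The variation level of a period is 100 x (period SB fraction) /
        (whole-day SB fraction); under equal period wear the whole-day
        fraction is the plain mean of the three period fractions, so the
        three values average to 100 within each day type.
        """
        out = []
        for d in DAY_TYPES:
            s = self.day_sb(d)
            out.extend(100.0 * self.sb_target[(d, p)] / s for p in PERIODS)
        return np.asarray(out)

    def variation_sds(self) -> np.ndarray:
        """Between-person SDs on the variation-level scale."""
        out = []
        for d in DAY_TYPES:
            s = self.day_sb(d)
            out.extend(100.0 * self.sb_sd[(d, p)] / s for p in PERIODS)
        return np.asarray(out)

    @classmethod
    def from_variation_profile(
        cls,
        name: str,
        day_sb_pct: dict,
        variation_mean: dict,
        variation_sd: dict,
        **kwargs,
    ) -> "ArchetypeProfile":
        """Build an archetype from a variation-level profile.

        ``day_sb_pct[day_type]`` is the whole-day sedentary percentage of
        wear (0-100); ``variation_mean``/``variation_sd`` map
        ``(day_type, period)`` to variation levels (~100).  The sedentary
        fraction targets are then ``day_sb x variation / 10^4``.
        """
        tgt = {
            (d, p): day_sb_pct[d] * variation_mean[(d, p)] / 1e4
            for d in DAY_TYPES
            for p in PERIODS
        }
        sd = {
            (d, p): day_sb_pct[d] * variation_sd[(d, p)] / 1e4
            for d in DAY_TYPES
            for p in PERIODS
        }
        return cls(name=name, sb_target=tgt, sb_sd=sd, **kwargs)


def _profile(day_sb, means, sds, name, **kw):
    dmap = dict(zip(DAY_TYPES, day_sb))
    keys = [(d, p) for d in DAY_TYPES for p in PERIODS]
    return ArchetypeProfile.from_variation_profile(
        name, dmap, dict(zip(keys, means)), dict(zip(keys, sds)), **kw
    )


def study_archetypes() -> list[ArchetypeProfile]:
    """The four published diurnal sedentary typologies.

    Variation-level means/SDs follow the reported cluster profiles
    (order: workday morning/afternoon/evening, then non-workday); within
    each day type the period means sum to 300, which pins down the one
    period whose mean is not printed.  Whole-day SB%-of-wear per day type
    and bout tempo / MVPA share come from the reported group summaries.
    """
    return [
        _profile(  # low fluctuation across the whole day, most sedentary
            (65.1, 64.2),
            [101.0, 106.1, 92.9, 100.9, 97.4, 101.7],
            [10.4, 8.0, 12.8, 12.5, 12.1, 12.9],
            "stable_sedentary",
            mean_bout_sed=7.5, mean_bout_active=4.1, mvpa_share=0.19,
        ),
        _profile(  # dip on non-workday mornings
            (62.4, 55.2),
            [93.5, 105.4, 101.1, 74.1, 104.4, 121.5],
            [10.1, 10.0, 10.1, 11.1, 12.3, 13.4],
            "off_morning_break",
            mean_bout_sed=6.7, mean_bout_active=4.4, mvpa_share=0.18,
        ),
        _profile(  # dip on non-workday afternoons
            (64.0, 47.4),
            [91.4, 109.8, 98.8, 84.9, 66.1, 149.0],
            [7.5, 7.7, 7.6, 20.6, 15.4, 25.8],
            "off_afternoon_break",
            mean_bout_sed=6.7, mean_bout_active=4.6, mvpa_share=0.20,
        ),
        _profile(  # evening spike on both day types
            (55.8, 59.1),
            [83.2, 91.6, 125.2, 88.0, 87.7, 124.3],
            [11.3, 13.2, 15.1, 13.3, 9.1, 17.4],
            "evening_sedentary",
            mean_bout_sed=6.0, mean_bout_active=4.7, mvpa_share=0.14,
        ),
    ]


#: Published cluster sizes 107/61/19/42 of 229, as mixture weights.
STUDY_MIXTURE_WEIGHTS = (107 / 229, 61 / 229, 19 / 229, 42 / 229)


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Sampling design of a simulated cohort.

    Defaults mirror the study protocol: a 7-day wear protocol yielding 5
    workdays + 2 non-workdays per participant, waking wear from about
    06:30 to 23:00, and occasional device-off gaps long enough for the
    non-wear detector to find.
    """

    n_participants: int = 229
    mixture_weights: tuple | None = None  # None -> uniform over archetypes
    n_workdays: int = 5
    n_nonworkdays: int = 2
    wake_start_mean: float = 390.0  # minutes of day (06:30)
    wake_start_sd: float = 30.0
    wake_end_mean: float = 1380.0  # 23:00
    wake_end_sd: float = 40.0
    nonwear_gap_rate: float = 0.3  # expected device-off gaps per day
    nonwear_gap_length: int = 75  # minutes; >=60 so the detector can see it
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.mixture_weights is not None:
            w = np.asarray(self.mixture_weights, float)
            if abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"mixture_weights sum to {w.sum():.12f}, expected 1"
                )
            if (w < 0).any():
                raise ConfigurationError("mixture_weights must be non-negative")
        if self.n_workdays < 0 or self.n_nonworkdays < 0:
            raise ConfigurationError("day counts must be non-negative")
        if self.wake_end_mean - self.wake_start_mean < 60:
            raise ConfigurationError("wake window shorter than 60 minutes")

    def weights(self, n_archetypes: int) -> np.ndarray:
        if self.mixture_weights is None:
            return np.full(n_archetypes, 1.0 / n_archetypes)
        w = np.asarray(self.mixture_weights, float)
        if len(w) != n_archetypes:
            raise ConfigurationError(
                f"{len(w)} mixture weights for {n_archetypes} archetypes"
            )
        return w


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    # one stream per participant so cohort-size changes never reshuffle
    # earlier participants
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# feature-level cohort
# ---------------------------------------------------------------------------


def generate_feature_cohort(
    config: CohortConfig, archetypes: list[ArchetypeProfile]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw variation-level feature vectors from the archetype mixture.

    Each participant's archetype label follows ``mixture_weights``; the six
    features are drawn independently per dimension from a normal with the
    archetype's implied variation-level mean and SD.

    Returns ``(features, labels)`` where *features* is an ``n x 6`` frame
    indexed by participant_id with :data:`FEATURE_COLUMNS` columns and
    *labels* the archetype index of each row.
    """
    if not archetypes:
        raise ConfigurationError("need at least one archetype")
    if config.n_participants < len(archetypes):
        warnings.warn(
            "fewer participants than archetypes; some components will be empty",
            stacklevel=2,
        )
    w = config.weights(len(archetypes))
    means = np.stack([a.variation_means() for a in archetypes])
    sds = np.stack([a.variation_sds() for a in archetypes])

    labels = np.empty(config.n_participants, dtype=int)
    feats = np.empty((config.n_participants, 6))
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i)
        lab = int(rng.choice(len(archetypes), p=w))
        labels[i] = lab
        feats[i] = rng.normal(means[lab], sds[lab])
    df = pd.DataFrame(
        feats, index=pd.Index(_participant_ids(config.n_participants), name="participant_id"),
        columns=list(FEATURE_COLUMNS),
    )
    return df, labels


# ---------------------------------------------------------------------------
# epoch-level cohort
# ---------------------------------------------------------------------------


def _truncnorm(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _simulate_day(
    rng: np.random.Generator,
    day_type: str,
    sb_frac: dict,
    archetype: ArchetypeProfile,
    config: CohortConfig,
    wake_start: int,
    wake_end: int,
) -> np.ndarray:
    """One 1440-minute METs vector for one participant-day."""
    mets = rng.uniform(0.2, 0.9, size=DAY_END)  # device off / asleep baseline

    cycle = archetype.mean_bout_sed + archetype.mean_bout_active
    # per-minute state chain over the wake window; parameters switch at the
    # clock-period boundaries so each period holds its stationary fraction
    n_wake = wake_end - wake_start
    minutes = np.arange(wake_start, wake_end)
    period_of = np.clip((minutes - WAKE_DAY_START) // 360, 0, 2)
    sb_by_min = np.array([sb_frac[(day_type, PERIODS[p])] for p in period_of])
    # mean bout lengths scaled to hit the target stationary fraction; the
    # archetype's cycle length is kept where both bouts stay >= 1 minute,
    # otherwise both are inflated together so the ratio (and hence the
    # stationary sedentary fraction) is preserved exactly
    bout_sed = sb_by_min * cycle
    bout_act = (1.0 - sb_by_min) * cycle
    shortest = np.minimum(bout_sed, bout_act)
    inflate = np.where(shortest < 1.0, 1.0 / shortest, 1.0)
    p_exit_sed = 1.0 / (bout_sed * inflate)
    p_exit_act = 1.0 / (bout_act * inflate)

    u_state = rng.random(n_wake)
    sed = np.empty(n_wake, dtype=bool)
    state = rng.random() < sb_by_min[0]
    for t in range(n_wake):
        sed[t] = state
        if state:
            if u_state[t] < p_exit_sed[t]:
                state = False
        else:
            if u_state[t] < p_exit_act[t]:
                state = True

    # sedentary wear epochs sit strictly above the non-wear allowance band
    # (<=1.0 METs) so worn time is identifiable from the stream
    vals = np.where(
        sed,
        rng.uniform(1.02, 1.5, size=n_wake),
        np.where(
            rng.random(n_wake) < archetype.mvpa_share,
            rng.uniform(3.0, 6.0, size=n_wake),
            rng.uniform(1.55, 2.95, size=n_wake),
        ),
    )
    mets[wake_start:wake_end] = vals

    # device-off gaps inside the wake window (low-MET runs the detector
    # must discover)
    n_gaps = rng.poisson(config.nonwear_gap_rate)
    for _ in range(n_gaps):
        g0 = int(rng.integers(wake_start, max(wake_start + 1, wake_end - 30)))
        g1 = min(g0 + config.nonwear_gap_length, DAY_END)
        mets[g0:g1] = rng.uniform(0.2, 0.9, size=g1 - g0)
    return mets


def generate_epoch_cohort(
    config: CohortConfig,
    archetypes: list[ArchetypeProfile],
    start_date: str = "2024-01-01",
):
    """Simulate minute-epoch METs streams for a whole cohort.

    Per participant-day: minutes outside the wake window (and injected
    device-off gaps) emit <=0.9 METs; within wear a two-state chain
    alternates sedentary bouts (METs in (0.9, 1.5]) with active bouts
    (METs in (1.5, 3.0), or >=3.0 with probability ``mvpa_share``), with
    period-specific stationary sedentary fractions drawn per participant
    around the archetype's targets.

    Returns ``(series_map, diary, labels)``: participant_id ->
    :class:`~sedpattern.processing.EpochSeries`, the day-type diary frame,
    and the true archetype indices.
    """
    from .processing import EpochSeries  # local import to avoid a cycle

    if not archetypes:
        raise ConfigurationError("need at least one archetype")
    w = config.weights(len(archetypes))
    pids = _participant_ids(config.n_participants)

    n_days = config.n_workdays + config.n_nonworkdays
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    day_types = ["workday"] * config.n_workdays + ["non_workday"] * config.n_nonworkdays

    series_map: dict[str, EpochSeries] = {}
    diary_rows = []
    labels = np.empty(config.n_participants, dtype=int)

    for i, pid in enumerate(pids):
        rng = _participant_rng(config.seed, i)
        lab = int(rng.choice(len(archetypes), p=w))
        labels[i] = lab
        arch = archetypes[lab]

        # participant-level period propensities (between-person variation)
        sb_frac = {}
        for d in DAY_TYPES:
            for p in PERIODS:
                v = rng.normal(arch.sb_target[(d, p)], arch.sb_sd[(d, p)])
                # open-interval clip keeps the bout chain non-degenerate
                sb_frac[(d, p)] = float(np.clip(v, 1e-9, 1.0 - 1e-9))

        day_vectors = []
        for date, dt in zip(dates, day_types):
            ws = int(_truncnorm(rng, config.wake_start_mean, config.wake_start_sd,
                                WAKE_DAY_START, DAY_END - 61))
            we = int(_truncnorm(rng, config.wake_end_mean, config.wake_end_sd,
                                ws + 60, DAY_END))
            day_vectors.append(
                _simulate_day(rng, dt, sb_frac, arch, config, ws, we)
            )
            diary_rows.append({"participant_id": pid, "date": date.date().isoformat(),
                               "day_type": dt})

        mets = np.concatenate(day_vectors)
        ts = pd.date_range(dates[0], periods=n_days * DAY_END, freq="min")
        series_map[pid] = EpochSeries(participant_id=pid, timestamps=ts, mets=mets)

    diary = pd.DataFrame(diary_rows)
    return series_map, diary, labels


# ---------------------------------------------------------------------------
# sociodemographic covariates
# ---------------------------------------------------------------------------


def generate_sociodemographic_table(
    labels: np.ndarray, category_specs: dict, seed: int
) -> pd.DataFrame:
    """Draw categorical covariates from cluster-conditional distributions.

    ``category_specs`` maps variable name -> ``{category: [p_cluster0,
    p_cluster1, ...]}``; per cluster the category probabilities must sum
    to 1.  Returns one row per participant (column per variable) indexed
    like *labels*.
    """
    labels = np.asarray(labels)
    n_clusters = int(labels.max()) + 1 if len(labels) else 0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    out = {}
    for var, spec in category_specs.items():
        cats = list(spec)
        probs = np.asarray([spec[c] for c in cats], float)  # c x k
        if probs.shape[1] < n_clusters:
            raise ConfigurationError(
                f"variable {var!r}: probabilities for {probs.shape[1]} clusters, "
                f"labels contain {n_clusters}"
            )
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ConfigurationError(
                f"variable {var!r}: per-cluster probabilities sum to {colsums}"
            )
        draws = np.empty(len(labels), dtype=object)
        for k in range(n_clusters):
            idx = np.flatnonzero(labels == k)
            if len(idx):
                draws[idx] = rng.choice(cats, size=len(idx), p=probs[:, k])
        out[var] = draws
    return pd.DataFrame(
        out, index=pd.Index(_participant_ids(len(labels)), name="participant_id")
    )


def study_covariate_specs() -> dict:
    """Cluster-conditional covariate distributions from the published
    participant-characteristics table (selected binary variables)."""
    return {
        "sex": {
            "women": [0.439, 0.393, 0.474, 0.690],
            "men": [0.561, 0.607, 0.526, 0.310],
        },
        "household_income": {
            "<5M yen": [0.346, 0.279, 0.053, 0.452],
            ">=5M yen": [0.654, 0.721, 0.947, 0.548],
        },
        "sleep_duration": {
            "<6 h": [0.607, 0.361, 0.368, 0.333],
            ">=6 h": [0.393, 0.639, 0.632, 0.667],
        },
        "marital_status": {
            "married": [0.757, 0.803, 0.737, 0.762],
            "single": [0.243, 0.197, 0.263, 0.238],
        },
    }


# ---------------------------------------------------------------------------
# recruitment fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecruitmentFixtureConfig:
    """Cohort with engineered, disjoint exclusion-filter failures."""

    n_total: int
    n_fail_wear: int = 0
    n_missing_work_sb: int = 0
    n_missing_covariates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_fail_wear, self.n_missing_work_sb, self.n_missing_covariates)
        if any(c < 0 for c in counts) or self.n_total < 0:
            raise ConfigurationError("counts must be non-negative")
        if sum(counts) > self.n_total:
            raise ConfigurationError(
                f"failure categories ({sum(counts)}) exceed n_total ({self.n_total})"
            )


@dataclass
class RecruitmentBundle:
    """Day-level records plus self-report and covariate tables."""

    day_records: pd.DataFrame  # participant_id, date, day_type, valid flags
    work_sb: pd.DataFrame  # participant_id, work_sb_min (may be NaN)
    covariates: pd.DataFrame  # participant_id, sex (may be NaN)


def generate_recruitment_fixture(config: RecruitmentFixtureConfig) -> RecruitmentBundle:
    """Build a cohort in which exactly the configured numbers of
    participants fail each exclusion filter.

    Wear failures have only 2 valid workdays and 1 valid non-workday (3
    valid days), failing both the >=4-valid-day and >=3-valid-workday
    rules; the other failure groups have complete accelerometer data but
    a missing work-domain self-report or sociodemographic field.  All
    remaining participants pass every filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 999]))
    pids = _participant_ids(config.n_total)
    fail_wear = set(pids[: config.n_fail_wear])
    miss_work = set(
        pids[config.n_fail_wear: config.n_fail_wear + config.n_missing_work_sb]
    )
    off = config.n_fail_wear + config.n_missing_work_sb
    miss_cov = set(pids[off: off + config.n_missing_covariates])

    day_rows = []
    for pid in pids:
        if pid in fail_wear:
            plan = [("workday", True)] * 2 + [("workday", False)] * 3 + [
                ("non_workday", True)
            ]
        else:
            plan = [("workday", True)] * 5 + [("non_workday", True)] * 2
        for j, (dt, valid) in enumerate(plan):
            wear = float(rng.normal(950, 60)) if valid else float(rng.uniform(100, 500))
            day_rows.append(
                {
                    "participant_id": pid,
                    "date": (pd.Timestamp("2024-01-01") + pd.Timedelta(days=j)).date().isoformat(),
                    "day_type": dt,
                    "wear_min_whole": round(max(wear, 0.0), 1),
                    "valid_day": valid,
                    "period_valid": valid,
                }
            )

    work_sb = pd.DataFrame(
        {
            "participant_id": pids,
            "work_sb_min": [
                np.nan if p in miss_work else float(np.round(rng.normal(420, 120), 1))
                for p in pids
            ],
        }
    )
    covariates = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": [
                None if p in miss_cov else rng.choice(["women", "men"]) for p in pids
            ],
        }
    )
    return RecruitmentBundle(
        day_records=pd.DataFrame(day_rows), work_sb=work_sb, covariates=covariates
    )
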