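"""Synthetic cohort generators: determinism, mixture behavior, epoch-level
fidelity, covariate tables and the recruitment fixture."""

import numpy as np
import pandas as pd
import pytest

from sedpattern import (
    CohortConfig,
    ConfigurationError,
    RecruitmentFixtureConfig,
    apply_exclusion_flow,
    generate_epoch_cohort,
    generate_feature_cohort,
    generate_recruitment_fixture,
    generate_sociodemographic_table,
    chi_square_test,
    process_cohort,
)
from sedpattern.synthetic import DAY_TYPES, PERIODS
from conftest import make_flat_archetype


# ---------------------------------------------------------------------------
# feature-level cohort
# ---------------------------------------------------------------------------


def test_degenerate_mixture_collapses_to_mean():
    arch = make_flat_archetype(sb=0.6, sd=1e-12)
    X, labels = generate_feature_cohort(CohortConfig(n_participants=8, seed=1), [arch])
    assert (labels == 0).all()
    np.testing.assert_allclose(X.to_numpy(), 100.0, atol=1e-6)


def test_feature_cohort_deterministic_under_seed(archetypes):
    cfg = CohortConfig(n_participants=30, seed=7)
    X1, l1 = generate_feature_cohort(cfg, archetypes)
    X2, l2 = generate_feature_cohort(cfg, archetypes)
    assert X1.equals(X2) and (l1 == l2).all()


def test_cohort_growth_preserves_existing_participants(archetypes):
    X1, _ = generate_feature_cohort(CohortConfig(n_participants=10, seed=7), archetypes)
    X2, _ = generate_feature_cohort(CohortConfig(n_participants=20, seed=7), archetypes)
    assert X1.equals(X2.iloc[:10])


def test_bad_mixture_weights_rejected():
    with pytest.raises(ConfigurationError):
        CohortConfig(n_participants=5, mixture_weights=(0.5, 0.4))


def test_fewer_participants_than_archetypes_warns(archetypes):
    with pytest.warns(UserWarning):
        generate_feature_cohort(CohortConfig(n_participants=2, seed=0), archetypes)


# ---------------------------------------------------------------------------
# epoch-level cohort
# ---------------------------------------------------------------------------


def test_epoch_cohort_deterministic_under_seed(archetypes):
    cfg = CohortConfig(n_participants=3, seed=11)
    s1, d1, l1 = generate_epoch_cohort(cfg, archetypes)
    s2, d2, l2 = generate_epoch_cohort(cfg, archetypes)
    assert d1.equals(d2) and (l1 == l2).all()
    for pid in s1:
        np.testing.assert_array_equal(s1[pid].mets, s2[pid].mets)


def test_diary_lists_every_date_exactly_once(small_epoch_cohort):
    _, diary, _ = small_epoch_cohort
    counts = diary.groupby(["participant_id", "date"]).size()
    assert (counts == 1).all()
    assert (diary.groupby("participant_id").size() == 7).all()


def test_no_gaps_full_window_gives_constant_wear(archetypes):
    cfg = CohortConfig(
        n_participants=4,
        nonwear_gap_rate=0.0,
        wake_start_mean=360.0,
        wake_start_sd=0.0,
        wake_end_mean=1440.0,
        wake_end_sd=0.0,
        seed=2,
    )
    series, diary, _ = generate_epoch_cohort(cfg, archetypes[:1])
    day = process_cohort(series, diary)
    assert (day["wear_min_whole"] == 1080).all()


def test_saturated_sedentary_target_gives_full_sb_percentage():
    arch = make_flat_archetype(sb=1 - 1e-9, sd=1e-12)
    cfg = CohortConfig(n_participants=2, nonwear_gap_rate=0.0, seed=3)
    series, diary, _ = generate_epoch_cohort(cfg, [arch])
    day = process_cohort(series, diary)
    for scope in ("whole", "morning", "afternoon", "evening"):
        pct = day[f"sb_pct_{scope}"].dropna()
        assert (pct == 100.0).all()


def test_stationary_sedentary_fraction_matches_target():
    # empirical SB fraction of wear within 3 SE of the archetype target,
    # per period, across >= 50 simulated participant-days
    arch = make_flat_archetype(sb=0.6, sd=1e-6)
    cfg = CohortConfig(
        n_participants=12, n_workdays=5, n_nonworkdays=2,
        nonwear_gap_rate=0.0, seed=9,
    )
    series, diary, _ = generate_epoch_cohort(cfg, [arch])
    day = process_cohort(series, diary)
    assert len(day) >= 50
    for p in PERIODS:
        frac = (day[f"sb_min_{p}"] / day[f"wear_min_{p}"]).dropna()
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.6) <= 3 * se


def test_short_wake_window_rejected():
    with pytest.raises(ConfigurationError):
        CohortConfig(wake_start_mean=1000.0, wake_end_mean=1040.0)


def test_degenerate_sedentary_target_rejected():
    with pytest.raises(ConfigurationError):
        make_flat_archetype(sb=1.0)
    with pytest.raises(ConfigurationError):
        make_flat_archetype(sb=0.0)


# ---------------------------------------------------------------------------
# sociodemographic tables
# ---------------------------------------------------------------------------


def test_certain_category_gives_constant_column():
    labels = np.array([0, 0, 1, 1, 1])
    spec = {"var": {"a": [1.0, 1.0], "b": [0.0, 0.0]}}
    tab = generate_sociodemographic_table(labels, spec, seed=0)
    assert (tab["var"] == "a").all()


def test_bad_cluster_probabilities_rejected():
    with pytest.raises(ConfigurationError):
        generate_sociodemographic_table(
            np.array([0, 1]), {"var": {"a": [0.5, 0.5], "b": [0.4, 0.5]}}, seed=0
        )


def test_cluster_conditional_proportions_converge():
    # law-of-large-numbers check at n = 10,000
    labels = np.r_[np.zeros(5000, int), np.ones(5000, int)]
    spec = {"sex": {"women": [0.439, 0.690], "men": [0.561, 0.310]}}
    tab = generate_sociodemographic_table(labels, spec, seed=1)
    for k, target in [(0, 0.439), (1, 0.690)]:
        got = (tab["sex"].to_numpy()[labels == k] == "women").mean()
        assert abs(got - target) < 0.02


def test_identical_distributions_rarely_significant():
    # null calibration: chi-square non-significant in >= 90% of 100 seeds
    rng = np.random.default_rng(0)
    labels = rng.choice(4, size=229, p=[107 / 229, 61 / 229, 19 / 229, 42 / 229])
    spec = {"var": {"a": [0.5] * 4, "b": [0.5] * 4}}
    nonsig = 0
    for seed in range(100):
        tab = generate_sociodemographic_table(labels, spec, seed=seed)
        counts = np.array(
            [[(tab["var"].to_numpy()[labels == k] == c).sum() for k in range(4)]
             for c in ("a", "b")]
        )
        if chi_square_test(counts).p >= 0.05:
            nonsig += 1
    assert nonsig >= 90


# ---------------------------------------------------------------------------
# recruitment fixture
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cfg, retained",
    [
        (RecruitmentFixtureConfig(10, 2, 1, 1, seed=0), 6),
        (RecruitmentFixtureConfig(5, 0, 0, 0, seed=0), 5),
    ],
)
def test_filter_chain_arithmetic(cfg, retained):
    manifest = apply_exclusion_flow(generate_recruitment_fixture(cfg))
    assert manifest["n_analyzed"] == retained
    assert (
        manifest["n_input"]
        - manifest["n_excluded_insufficient_accelerometer"]
        - manifest["n_excluded_missing_work_sb"]
        - manifest["n_excluded_missing_covariates"]
        == manifest["n_analyzed"]
    )


def test_overlapping_failure_counts_rejected():
    with pytest.raises(ConfigurationError):
        RecruitmentFixtureConfig(5, 3, 2, 1)
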