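"""Synthetic study generator: allocation balance, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from polyadhere import _vocab
from polyadhere.config import StudyConfig
from polyadhere.eligibility import filter_therapies
from polyadhere.engine import build_patient_timelines, adherence_tables
from polyadhere.synthetic import (
    ExclusionRates,
    block_randomise,
    generate_cohort,
    simulate_change_trial,
    simulate_dispensing,
    simulate_drps,
    simulate_study,
    simulate_surveys,
)

NO_EXCLUSIONS = ExclusionRates(0, 0, 0, 0)


def test_block_of_eight_is_exactly_balanced():
    for seed in (0, 1, 99):
        alloc = block_randomise({"PH1": [f"P{i}" for i in range(8)]}, seed=seed)
        counts = alloc["arm"].value_counts()
        assert counts["intervention"] == 4
        assert counts["control"] == 4


def test_single_patient_gets_one_arm():
    alloc = block_randomise({"PH1": ["P1"]}, seed=3)
    assert len(alloc) == 1
    assert alloc.loc[0, "arm"] in ("intervention", "control")


def test_running_imbalance_never_exceeds_four():
    """Exhaustive check over generated sequences, seeds 1..100."""
    for seed in range(1, 101):
        n = 100
        alloc = block_randomise({"PH1": [f"P{i}" for i in range(n)]}, seed=seed)
        running = np.cumsum(np.where(alloc["arm"] == "intervention", 1, -1))
        assert np.abs(running).max() <= 4


def test_allocation_is_deterministic_and_block_structured():
    patients = {"PH1": [f"A{i}" for i in range(11)], "PH2": [f"B{i}" for i in range(5)]}
    a1 = block_randomise(patients, seed=42)
    a2 = block_randomise(patients, seed=42)
    pd.testing.assert_frame_equal(a1, a2)
    # completed blocks of eight hold exactly four per arm
    full = a1[(a1["pharmacy_id"] == "PH1") & (a1["block_index"] == 0)]
    assert (full["arm"] == "intervention").sum() == 4
    assert sorted(full["position_in_block"]) == list(range(1, 9))


def test_every_patient_has_at_least_four_therapies():
    cfg = StudyConfig(rng_seed=1)
    cohort = generate_cohort(cfg, n_pharmacies=2, n_patients=20)
    assert cohort.regimen.groupby("patient_id").size().min() >= 4
    assert set(cohort.regimen["patient_id"]) == set(cohort.patients["patient_id"])


def test_zero_exclusion_rates_yield_fully_eligible_cohort():
    cfg = StudyConfig(rng_seed=2)
    cohort = generate_cohort(
        cfg, n_pharmacies=2, n_patients=25, exclusion_rates=NO_EXCLUSIONS, dropout_rate=0.0
    )
    dispensing = simulate_dispensing(cohort, cfg)
    decisions = filter_therapies(cohort.regimen, cohort.drug_master, dispensing, cfg)
    assert decisions["eligible"].all()


def test_same_seed_gives_identical_study(tmp_path):
    cfg = StudyConfig(rng_seed=9)
    _, bundle1, drps1 = simulate_study(cfg, n_pharmacies=3, n_patients=12)
    _, bundle2, drps2 = simulate_study(cfg, n_pharmacies=3, n_patients=12)
    for name, df1 in bundle1.tables().items():
        pd.testing.assert_frame_equal(df1, getattr(bundle2, name))
    pd.testing.assert_frame_equal(drps1, drps2)


def test_invalid_distribution_parameters_signalled():
    cfg = StudyConfig(rng_seed=0)
    with pytest.raises(ValueError):
        generate_cohort(cfg, n_patients=5, adherence_distribution=("beta", -1, 2))
    with pytest.raises(ValueError):
        generate_cohort(cfg, n_patients=5, adherence_distribution=("fixed", 1.5))
    with pytest.raises(ValueError):
        generate_cohort(cfg, n_patients=5, adherence_distribution=("weird", 1))


def test_dispensing_dates_within_study_horizon():
    cfg = StudyConfig(rng_seed=4)
    cohort = generate_cohort(cfg, n_pharmacies=3, n_patients=30)
    dispensing = simulate_dispensing(cohort, cfg)
    days = dispensing["dispense_date"].map(cfg.day_offset)
    assert days.min() >= -cfg.lookback_days
    assert days.max() < cfg.window_days


def test_every_therapy_redeemed_before_baseline():
    cfg = StudyConfig(rng_seed=4)
    cohort = generate_cohort(cfg, n_pharmacies=3, n_patients=30)
    dispensing = simulate_dispensing(cohort, cfg)
    pre = dispensing[[cfg.day_offset(d) < 0 for d in dispensing["dispense_date"]]]
    therapies = set(zip(cohort.regimen["patient_id"], cohort.regimen["product_id"]))
    assert therapies <= set(zip(pre["patient_id"], pre["product_id"]))


def test_no_dispensing_after_dropout_day():
    cfg = StudyConfig(rng_seed=6)
    cohort = generate_cohort(cfg, n_pharmacies=2, n_patients=40, dropout_rate=0.5)
    dispensing = simulate_dispensing(cohort, cfg)
    dropout = dict(zip(cohort.patients["patient_id"], cohort.patients["dropout_day"]))
    for row in dispensing.itertuples():
        d = dropout[row.patient_id]
        if d is not None and not pd.isna(d):
            assert cfg.day_offset(row.dispense_date) <= int(d)


def test_full_availability_means_no_stockout_day():
    cfg = StudyConfig(rng_seed=8)
    cohort = generate_cohort(
        cfg,
        n_pharmacies=1,
        n_patients=10,
        adherence_distribution=("fixed", 1.0),
        exclusion_rates=NO_EXCLUSIONS,
        dropout_rate=0.0,
    )
    dispensing = simulate_dispensing(cohort, cfg)
    decisions = filter_therapies(cohort.regimen, cohort.drug_master, dispensing, cfg)
    timelines = build_patient_timelines(
        cohort.regimen, dispensing, cohort.drug_master, decisions, cfg
    )
    assert all(tl.available.all() for tl in timelines)


def test_mean_covered_fraction_tracks_true_availability():
    """Monte-Carlo check of the stock-out model against its own target."""
    cfg = StudyConfig(rng_seed=7)
    cohort = generate_cohort(
        cfg,
        n_pharmacies=10,
        n_patients=500,
        adherence_distribution=("fixed", 0.7),
        exclusion_rates=NO_EXCLUSIONS,
        dropout_rate=0.0,
    )
    dispensing = simulate_dispensing(cohort, cfg)
    decisions = filter_therapies(cohort.regimen, cohort.drug_master, dispensing, cfg)
    timelines = build_patient_timelines(
        cohort.regimen, dispensing, cohort.drug_master, decisions, cfg
    )
    covered = np.mean([tl.available.mean() for tl in timelines])
    assert 0.68 <= covered <= 0.72


def test_surveys_bounded_and_near_ceiling():
    cfg = StudyConfig(rng_seed=3)
    cohort = generate_cohort(cfg, n_pharmacies=5, n_patients=100, dropout_rate=0.0)
    surveys = simulate_surveys(cohort, cfg)
    vas = surveys["vas"].dropna()
    assert (vas >= 0).all() and (vas <= 100).all()
    # truncating N(96, 8) at the 100-ceiling puts the analytic mean near
    # 91.9 (= 96 - 8 * lambda(0.5)); check the sample lands around it
    baseline = surveys.loc[surveys["timepoint"] == "T0", "vas"].dropna()
    assert 89 <= baseline.mean() <= 95


def test_zero_arm_effect_leaves_arms_comparable():
    cfg = StudyConfig(rng_seed=13)
    cohort = generate_cohort(cfg, n_pharmacies=5, n_patients=300, dropout_rate=0.0)
    surveys = simulate_surveys(cohort, cfg, arm_effect=0.0)
    arm = dict(zip(cohort.allocation["patient_id"], cohort.allocation["arm"]))
    t2 = surveys[surveys["timepoint"] == "T2"].dropna(subset=["vas"])
    means = t2.groupby(t2["patient_id"].map(arm))["vas"].mean()
    assert abs(means["intervention"] - means["control"]) < 2.5


def test_arm_effect_recovered_away_from_ceiling():
    """Generator self-consistency: the induced mean change difference
    matches the injected effect within Monte-Carlo error (baseline kept
    off the ceiling so clipping cannot attenuate it)."""
    diffs = []
    for rep in range(20):
        table_free = simulate_change_trial(
            200, 1.03, seed=1000 + rep, baseline_mean=88.0, baseline_sd=6.0
        )
        diffs.append(table_free)
    # aggregate improved-vs-worsened asymmetry favours the intervention
    total = np.sum(diffs, axis=0)
    assert total[0, 0] > total[0, 1]  # intervention: improved > worsened
    # direct mean-change recovery
    rng = np.random.default_rng(55)
    from polyadhere.synthetic import _truncnorm

    n = 4000
    latent = _truncnorm(rng, 88.0, 6.0, 0, 100, 2 * n)
    effect = np.where(np.arange(2 * n) < n, 1.03, 0.0)
    v0 = np.clip(latent + rng.normal(0, 4.0, 2 * n), 0, 100)
    v2 = np.clip(latent + rng.normal(0, 4.0, 2 * n) + effect, 0, 100)
    delta = v2 - v0
    diff = delta[:n].mean() - delta[n:].mean()
    se = np.sqrt(delta[:n].var() / n + delta[n:].var() / n)
    assert abs(diff - 1.03) < 3 * se + 0.05


def test_drp_records_use_closed_vocabularies():
    cfg = StudyConfig(rng_seed=21)
    cohort = generate_cohort(cfg, n_pharmacies=3, n_patients=60)
    drps = simulate_drps(cohort, cfg)
    assert set(drps["cause"]) <= set(_vocab.DRP_CAUSES)
    assert set(drps["intervention"]) <= set(_vocab.DRP_INTERVENTIONS)
    assert set(drps["urgency"]) <= set(_vocab.DRP_URGENCY)
    interv = set(cohort.allocation.loc[cohort.allocation["arm"] == "intervention", "patient_id"])
    assert set(drps["patient_id"]) <= interv
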