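"""Adherence engine: carry-over loop, MPR/DPPR, oracle equivalence."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyadhere.engine import (
    build_timeline,
    classify_nonadherence,
    compute_dppr,
    compute_mpr,
)

from conftest import (
    brute_force_availability,
    brute_force_dppr,
    random_histories,
    small_config,
)


def test_single_baseline_dispensing_covers_first_hundred_days(config):
    tl = build_timeline("P", "D", 1, [(0, 100)], config)
    assert tl.carry_in_units == 0
    assert tl.available[:100].all()
    assert not tl.available[100:].any()


def test_lookback_carry_over_credits_leftover_stock(config):
    # 120 units dispensed 60 days pre-baseline at 1/day: 60 consumed in
    # the look-back, 60 carried in, covering days 0-59
    tl = build_timeline("P", "D", 1, [(-60, 120)], config)
    assert tl.carry_in_units == 60
    assert tl.available[:60].all()
    assert not tl.available[60:].any()


def test_dispensing_after_window_end_ignored(config):
    base = build_timeline("P", "D", 1, [(0, 50)], config)
    with_late = build_timeline("P", "D", 1, [(0, 50), (config.window_days, 100)], config)
    assert np.array_equal(base.available, with_late.available)


def test_uncovered_days_do_not_consume_stock(config):
    # 10 units at day 0, nothing until day 50: days 0-9 covered, then a
    # refill at day 50 resumes coverage with no stock lost in the gap
    tl = build_timeline("P", "D", 1, [(0, 10), (50, 10)], config)
    assert tl.available[:10].all()
    assert not tl.available[10:50].any()
    assert tl.available[50:60].all()


def test_half_tablet_doses_exact(config):
    # 30 units at 1/2 per day last exactly 60 days
    tl = build_timeline("P", "D", Fraction(1, 2), [(0, 30)], config)
    assert tl.covered_days == 60


def test_zero_dose_rejected(config):
    with pytest.raises(ValueError):
        build_timeline("P", "D", 0, [(0, 10)], config)


def test_mpr_full_coverage(config):
    tl = build_timeline("P", "D", 1, [(0, 196)], config)
    res = compute_mpr(tl, config)
    assert res.mpr_percent == 100.0
    assert not res.nonadherent


def test_mpr_hundred_of_196_days(config):
    tl = build_timeline("P", "D", 1, [(0, 100)], config)
    res = compute_mpr(tl, config)
    assert round(res.mpr_percent, 1) == 51.0
    assert res.nonadherent


def test_nonadherence_cutoff_is_strict():
    summary = classify_nonadherence([100.0, 80.0, 79.99], cutoff=80.0)
    assert summary.n_nonadherent == 1
    assert summary.n_adherent == 2
    assert classify_nonadherence([79.9], 80.0).n_nonadherent == 1
    assert classify_nonadherence([80.0], 80.0).n_nonadherent == 0


def test_mpr_cap_flag_controls_oversupply(config):
    # 400 units at 1/day in a 196-day window: capped 100, uncapped >100
    tl = build_timeline("P", "D", 1, [(0, 400)], config)
    capped = compute_mpr(tl, config)
    assert capped.mpr_percent == 100.0
    uncapped_cfg = type(config).from_dict({**config.to_dict(), "mpr_cap_enabled": False})
    uncapped = compute_mpr(tl, uncapped_cfg)
    assert uncapped.mpr_percent == pytest.approx(100 * 400 / 196)


def test_dppr_single_medication_equals_mpr(config):
    tl = build_timeline("P", "D", 1, [(0, 100)], config)
    assert compute_dppr([tl], config).dppr_percent == compute_mpr(tl, config).mpr_percent


def test_dppr_two_medications_toy_window():
    cfg = small_config(window_days=10)
    full = build_timeline("P", "A", 1, [(0, 10)], cfg)
    half = build_timeline("P", "B", 1, [(0, 5)], cfg)
    res = compute_dppr([full, half], cfg)
    assert res.dppr_percent == 75.0
    assert res.n_medications == 2


def test_dppr_full_coverage_is_hundred():
    cfg = small_config(window_days=10)
    tls = [build_timeline("P", f"D{i}", 1, [(0, 10)], cfg) for i in range(3)]
    assert compute_dppr(tls, cfg).dppr_percent == 100.0


def test_dppr_requires_timelines(config):
    with pytest.raises(ValueError):
        compute_dppr([], config)


def test_dppr_rejects_mixed_patients(config):
    a = build_timeline("P1", "D", 1, [(0, 10)], config)
    b = build_timeline("P2", "D", 1, [(0, 10)], config)
    with pytest.raises(ValueError):
        compute_dppr([a, b], config)


def test_engine_matches_brute_force_oracle_on_random_histories():
    """Exact equality against the per-(medication, day) matrix oracle."""
    for window, lookback, therapies in random_histories(500, seed=2024):
        cfg = small_config(window_days=window, lookback_days=lookback)
        timelines = [
            build_timeline("P", f"D{i}", dose, disp, cfg)
            for i, (disp, dose) in enumerate(therapies)
        ]
        for tl, (disp, dose) in zip(timelines, therapies):
            expected = brute_force_availability(disp, dose, window, lookback)
            assert tl.available.tolist() == expected
        got = compute_dppr(timelines, cfg).dppr_percent
        assert got == brute_force_dppr(therapies, window, lookback)


dispensing_strategy = st.lists(
    st.tuples(st.integers(-40, 60), st.integers(1, 50)), min_size=0, max_size=6
)


@settings(max_examples=200, derandomize=True)
@given(disp=dispensing_strategy, extra=st.tuples(st.integers(-40, 49), st.integers(1, 50)))
def test_adding_a_dispensing_never_decreases_coverage(disp, extra):
    cfg = small_config(window_days=50, lookback_days=40)
    before = build_timeline("P", "D", 1, disp, cfg).covered_days
    after = build_timeline("P", "D", 1, disp + [extra], cfg).covered_days
    assert after >= before


@settings(max_examples=200, derandomize=True)
@given(
    disp=dispensing_strategy,
    dose=st.sampled_from([Fraction(1, 2), Fraction(1), Fraction(2), Fraction(3, 2)]),
)
def test_supply_conservation_and_bounds(disp, dose):
    cfg = small_config(window_days=50, lookback_days=40)
    tl = build_timeline("P", "D", dose, disp, cfg)
    # consumed in window cannot exceed carry-in plus in-window supply
    assert tl.covered_days * dose <= tl.carry_in_units + tl.units_in_window
    res = compute_mpr(tl, cfg)
    assert 0.0 <= res.mpr_percent <= 100.0
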