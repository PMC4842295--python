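"""Shared fixtures: toy study tables and independent brute-force oracles."""

from __future__ import annotations

import datetime as dt
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from polyadhere.config import StudyConfig
from polyadhere.io import TABLE_SCHEMAS


@pytest.fixture
def config() -> StudyConfig:
    return StudyConfig(baseline_date=dt.date(2013, 1, 1), rng_seed=0)


def small_config(window_days: int, lookback_days: int = 30) -> StudyConfig:
    """A toy-window config for hand-simulated timelines."""
    return StudyConfig(
        window_days=window_days,
        lookback_days=lookback_days,
        survey_offsets=(1, 2, min(3, window_days)),
    )


# -- independent day-by-day availability oracle ---------------------------


def brute_force_availability(
    dispensings: list[tuple[int, int]],
    daily_dose,
    window_days: int,
    lookback_days: int,
) -> list[bool]:
    """Materialise the per-day availability of one therapy.

    Deliberately naive: exact Fraction stock, a dict of dispensed units
    per day, one pass over every day.  Kept independent of the engine's
    implementation as the reference for oracle-equivalence tests.
    """
    dose = Fraction(str(daily_dose))
    by_day: dict[int, int] = {}
    for day, units in dispensings:
        if -lookback_days <= day < window_days:
            by_day[day] = by_day.get(day, 0) + units
    stock = Fraction(0)
    available = []
    for day in range(-lookback_days, window_days):
        stock += by_day.get(day, 0)
        if stock >= dose:
            stock -= dose
            covered = True
        else:
            covered = False
        if day >= 0:
            available.append(covered)
    return available


def brute_force_dppr(
    therapies: list[tuple[list[tuple[int, int]], object]],
    window_days: int,
    lookback_days: int,
) -> float:
    """DPPR via the full (medication, day) availability matrix."""
    matrix = [
        brute_force_availability(disp, dose, window_days, lookback_days)
        for disp, dose in therapies
    ]
    total = sum(sum(row) for row in matrix)
    return 100.0 * total / (len(matrix) * window_days)


# -- hand-enumerated eligibility fixture ----------------------------------


def eligibility_fixture(config: StudyConfig):
    """Ten therapies for one patient set; five survive the filter.

    Exclusions: two dose changes, one topical form, one on-demand ATC
    (M01AE01), one therapy never redeemed before baseline.
    """
    drug_rows = [
        ("D01", "C07AB02", 100, "oral_solid"),
        ("D02", "C10AA01", 100, "oral_solid"),
        ("D03", "A02BC01", 30, "oral_solid"),
        ("D04", "C09AA02", 100, "oral_solid"),
        ("D05", "A10BA02", 100, "oral_solid"),
        ("D06", "C03CA01", 30, "oral_solid"),
        ("D07", "C08CA01", 100, "oral_solid"),
        ("D08", "D07AC01", 30, "topical"),
        ("D09", "M01AE01", 30, "oral_solid"),
        ("D10", "N06AB06", 30, "oral_solid"),
    ]
    drug_master = pd.DataFrame(
        drug_rows, columns=["product_id", "atc_code", "package_size", "form"]
    )

    def therapy(pid, dose_changed=False):
        return {
            "patient_id": "P1",
            "product_id": pid,
            "daily_dose": Fraction(1),
            "regimen_type": "daily_fixed",
            "dose_changed_in_window": dose_changed,
            "self_dispensing_prescriber": False,
            "redeemed_before_baseline": True,
            "reported_change": "dosage_change" if dose_changed else "no_change",
        }

    regimen = pd.DataFrame(
        [
            therapy("D01"),
            therapy("D02"),
            therapy("D03"),
            therapy("D04"),
            therapy("D05"),
            therapy("D06", dose_changed=True),
            therapy("D07", dose_changed=True),
            therapy("D08"),  # topical
            therapy("D09"),  # on-demand ATC class
            therapy("D10"),  # never redeemed pre-baseline (no dispensing row)
        ],
        columns=TABLE_SCHEMAS["regimen"],
    )

    pre = config.baseline_date - dt.timedelta(days=30)
    dispensing = pd.DataFrame(
        [
            {
                "patient_id": "P1",
                "product_id": pid,
                "dispense_date": pre,
                "packages": 1,
            }
            for pid in ["D01", "D02", "D03", "D04", "D05", "D06", "D07", "D08", "D09"]
        ],
        columns=TABLE_SCHEMAS["dispensing"],
    )
    expected_eligible = {"D01", "D02", "D03", "D04", "D05"}
    expected_reasons = {
        "D06": ("DOSE_CHANGED",),
        "D07": ("DOSE_CHANGED",),
        "D08": ("FORM_EXCLUDED",),
        "D09": ("ON_DEMAND_ATC",),
        "D10": ("NOT_REDEEMED_PRE_BASELINE",),
    }
    return drug_master, regimen, dispensing, expected_eligible, expected_reasons


def random_histories(
    n: int, seed: int, max_therapies: int = 5, max_window: int = 50
):
    """Random multi-therapy dispensing histories for oracle checks."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        window = int(rng.integers(5, max_window + 1))
        lookback = int(rng.integers(5, 40))
        n_ther = int(rng.integers(1, max_therapies + 1))
        therapies = []
        for _ in range(n_ther):
            dose = Fraction(int(rng.integers(1, 5)), int(rng.integers(1, 3)))
            n_disp = int(rng.integers(0, 6))
            disp = [
                (
                    int(rng.integers(-lookback - 5, window + 5)),
                    int(rng.integers(1, 40)),
                )
                for _ in range(n_disp)
            ]
            therapies.append((disp, dose))
        yield window, lookback, therapies
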