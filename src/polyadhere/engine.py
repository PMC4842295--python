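"""Supply timelines with pre-baseline carry-over; MPR and DPPR.

The engine turns a therapy's refill history into a day-level supply
timeline and derives the two objective adherence metrics:

* **MPR** (Medication Possession Ratio), per therapy: days' supply
  available divided by the days in the observation window.
* **DPPR** (Daily Polypharmacy Possession Ratio), per patient: the
  average over observation days of the fraction of the patient's
  eligible medications with supply available that day.

Carry-over semantics
--------------------
The stock simulation starts ``lookback_days`` (default 200) before
baseline so that supply from pre-baseline refills is credited to the
window — a patient already on therapy at study start is not penalised
for refilling late in the look-back period.  Stock evolves day by day:

* dispensed units are added on the dispense date;
* a day is *covered* iff stock >= daily dose, in which case one dose is
  consumed; uncovered days do not consume stock;
* unused stock persists indefinitely within the study horizon and
  stacks across refills.

Partial days are not granted: stock below one daily dose leaves the day
uncovered.  All arithmetic is exact (integer units scaled by the dose
denominator), so half-tablet regimens incur no float drift.

The day convention is half-open: the window is ``[T-0, T-0 + window)``,
the look-back ``[T-0 - lookback, T-0)``; a dispensing on the baseline
date is in-window.  Dispensings after window end are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import join_package_size

__all__ = [
    "SupplyTimeline",
    "MPRResult",
    "DPPRResult",
    "ClassificationSummary",
    "build_timeline",
    "build_patient_timelines",
    "compute_mpr",
    "compute_dppr",
    "classify_nonadherence",
    "adherence_tables",
]


@dataclass(frozen=True)
class SupplyTimeline:
    """Per-day availability of one therapy over the observation window."""

    patient_id: str
    product_id: str
    daily_dose: Fraction
    #: stock at the start of the baseline day, from look-back refills
    carry_in_units: Fraction
    #: covered status for each of the window's days (day 0 = baseline)
    available: np.ndarray
    #: units dispensed inside the window (for the uncapped supply ratio)
    units_in_window: int

    @property
    def covered_days(self) -> int:
        return int(self.available.sum())


@dataclass(frozen=True)
class MPRResult:
    patient_id: str
    product_id: str
    mpr_percent: float
    covered_days: int
    nonadherent: bool


@dataclass(frozen=True)
class DPPRResult:
    patient_id: str
    dppr_percent: float
    n_medications: int
    nonadherent: bool


def build_timeline(
    patient_id: str,
    product_id: str,
    daily_dose: Fraction | int | float | str,
    dispensings: Iterable[tuple[int, int]],
    config: StudyConfig,
) -> SupplyTimeline:
    """Simulate the stock loop for one therapy.

    Parameters
    ----------
    daily_dose
        Positive dose in units/day; exact rationals supported.
    dispensings
        Iterable of ``(day_offset, units)`` pairs, day offsets relative
        to baseline (negative = look-back).  Dispensings before the
        look-back start or after window end are ignored.
    """
    dose = Fraction(str(daily_dose)) if not isinstance(daily_dose, Fraction) else daily_dose
    if dose <= 0:
        raise ValueError("daily_dose must be positive (ineligible therapy reached engine)")

    window = config.window_days
    lookback = config.lookback_days
    # integer arithmetic: scale stock by the dose denominator
    scale = dose.denominator
    dose_scaled = dose.numerator

    units_by_day: dict[int, int] = {}
    units_in_window = 0
    for day, units in dispensings:
        day = int(day)
        units = int(units)
        if day < -lookback or day >= window:
            continue
        units_by_day[day] = units_by_day.get(day, 0) + units
        if day >= 0:
            units_in_window += units

    stock = 0  # scaled units
    carry_in = Fraction(0)
    available = np.zeros(window, dtype=bool)
    for day in range(-lookback, window):
        if day == 0:
            carry_in = Fraction(stock, scale)
        stock += units_by_day.get(day, 0) * scale
        if stock >= dose_scaled:
            stock -= dose_scaled
            if day >= 0:
                available[day] = True
    return SupplyTimeline(
        patient_id=patient_id,
        product_id=product_id,
        daily_dose=dose,
        carry_in_units=carry_in,
        available=available,
        units_in_window=units_in_window,
    )


def build_patient_timelines(
    regimen: pd.DataFrame,
    dispensing: pd.DataFrame,
    drug_master: pd.DataFrame,
    decisions: pd.DataFrame,
    config: StudyConfig,
) -> list[SupplyTimeline]:
    """Build timelines for every eligible therapy in the tables."""
    annotated = join_package_size(dispensing, drug_master)
    annotated = annotated.assign(
        day=[config.day_offset(d) for d in annotated["dispense_date"]]
    )
    by_therapy: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for row in annotated.itertuples():
        by_therapy.setdefault((row.patient_id, row.product_id), []).append(
            (row.day, row.units_dispensed)
        )

    eligible = decisions.loc[decisions["eligible"], ["patient_id", "product_id"]]
    eligible_keys = set(zip(eligible["patient_id"], eligible["product_id"]))

    timelines = []
    for row in regimen.itertuples():
        key = (row.patient_id, row.product_id)
        if key not in eligible_keys:
            continue
        timelines.append(
            build_timeline(
                row.patient_id,
                row.product_id,
                row.daily_dose,
                by_therapy.get(key, []),
                config,
            )
        )
    return timelines


def compute_mpr(timeline: SupplyTimeline, config: StudyConfig) -> MPRResult:
    """MPR of one therapy: covered days / window days, as a percentage.

    With capping enabled (default) the ratio is the fraction of window
    days with supply available, inherently bounded by 100.  With capping
    disabled the raw supply ratio is reported instead — total days'
    supply on hand (carry-in plus in-window dispensings, in doses)
    divided by the window length — which can exceed 100 under
    oversupply.
    """
    window = config.window_days
    covered = timeline.covered_days
    if config.mpr_cap_enabled:
        mpr = 100.0 * covered / window
    else:
        supply_days = (timeline.carry_in_units + timeline.units_in_window) / timeline.daily_dose
        mpr = 100.0 * float(supply_days) / window
    return MPRResult(
        patient_id=timeline.patient_id,
        product_id=timeline.product_id,
        mpr_percent=mpr,
        covered_days=covered,
        nonadherent=mpr < config.nonadherence_cutoff,
    )


def compute_dppr(
    timelines: Sequence[SupplyTimeline], config: StudyConfig
) -> DPPRResult:
    """DPPR of one patient from the timelines of their eligible therapies.

    Equals ``100 * (total covered medication-days) / (n_medications *
    window_days)`` — equivalently the mean over days of the fraction of
    medications available that day.  With a single medication it
    collapses to that therapy's (capped) MPR.
    """
    if not timelines:
        raise ValueError("compute_dppr requires at least one eligible timeline")
    patient_ids = {t.patient_id for t in timelines}
    if len(patient_ids) != 1:
        raise ValueError(f"timelines span several patients: {sorted(patient_ids)}")
    window = config.window_days
    n_meds = len(timelines)
    covered_med_days = int(sum(t.covered_days for t in timelines))
    dppr = 100.0 * covered_med_days / (n_meds * window)
    return DPPRResult(
        patient_id=next(iter(patient_ids)),
        dppr_percent=dppr,
        n_medications=n_meds,
        nonadherent=dppr < config.nonadherence_cutoff,
    )


@dataclass(frozen=True)
class ClassificationSummary:
    """Adherent/non-adherent partition below a strict percentage cut-off."""

    n: int
    n_nonadherent: int
    cutoff: float

    @property
    def n_adherent(self) -> int:
        return self.n - self.n_nonadherent

    @property
    def pct_nonadherent(self) -> float:
        return 100.0 * self.n_nonadherent / self.n


def classify_nonadherence(
    values: Sequence[float], cutoff: float
) -> ClassificationSummary:
    """Partition adherence percentages by the strict ``< cutoff`` rule."""
    values = list(values)
    if not values:
        raise ValueError("classify_nonadherence requires at least one value")
    below = sum(1 for v in values if v < cutoff)
    return ClassificationSummary(n=len(values), n_nonadherent=below, cutoff=cutoff)


def adherence_tables(
    timelines: Sequence[SupplyTimeline], config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-therapy MPR table and per-patient DPPR table.

    Full-precision percentages; round to one decimal only in reports.
    """
    mpr_rows = []
    by_patient: dict[str, list[SupplyTimeline]] = {}
    for tl in timelines:
        res = compute_mpr(tl, config)
        mpr_rows.append(
            {
                "patient_id": res.patient_id,
                "product_id": res.product_id,
                "mpr_percent": res.mpr_percent,
                "covered_days": res.covered_days,
                "carry_in_units": float(tl.carry_in_units),
                "nonadherent": res.nonadherent,
            }
        )
        by_patient.setdefault(tl.patient_id, []).append(tl)

    dppr_rows = []
    for patient_id, tls in by_patient.items():
        res = compute_dppr(tls, config)
        dppr_rows.append(
            {
                "patient_id": patient_id,
                "dppr_percent": res.dppr_percent,
                "n_medications": res.n_medications,
                "nonadherent": res.nonadherent,
            }
        )
    mpr_cols = [
        "patient_id", "product_id", "mpr_percent", "covered_days", "carry_in_units", "nonadherent",
    ]
    dppr_cols = ["patient_id", "dppr_percent", "n_medications", "nonadherent"]
    return (
        pd.DataFrame(mpr_rows, columns=mpr_cols),
        pd.DataFrame(dppr_rows, columns=dppr_cols),
    )
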