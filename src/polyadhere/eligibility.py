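"""Therapy-level eligibility rules for refill-based adherence calculation.

A therapy enters the MPR calculation only when the refill record can be
interpreted as a continuous daily regimen: the patient must report daily
use over the whole observation period, the form must be oral with a
definite dosage, at least one prescription must have been redeemed
strictly before baseline, and therapies prescribed by self-dispensing
physicians, dose-changed during the window, or belonging to chronic
on-demand ATC classes (pain killers N02/M01A, anxiolytics N05BA,
magnesium A12CC) are excluded, as are creams and drops whose dosing
cannot be pinned down.  A patient is DPPR-eligible when at least one of
their therapies survives the filter.

Decisions are explainable: every ineligible therapy carries the full list
of violated rule codes, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import pandas as pd

from . import _vocab
from .config import StudyConfig

__all__ = [
    "REASON_CODES",
    "EligibilityDecision",
    "evaluate_therapy",
    "filter_therapies",
    "eligible_patients",
]

#: Closed set of exclusion-rule codes.
REASON_CODES = (
    "NOT_DAILY",
    "NOT_ORAL",
    "NO_DEFINITE_DOSE",
    "NOT_REDEEMED_PRE_BASELINE",
    "SELF_DISPENSING",
    "DOSE_CHANGED",
    "ON_DEMAND_ATC",
    "FORM_EXCLUDED",
)


@dataclass(frozen=True)
class EligibilityDecision:
    patient_id: str
    product_id: str
    eligible: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.eligible == (len(self.reasons) == 0)
        assert all(r in REASON_CODES for r in self.reasons)


def evaluate_therapy(
    *,
    regimen_type: str,
    form: str,
    atc_code: str,
    daily_dose: Fraction | float | None,
    has_pre_baseline_dispensing: bool,
    self_dispensing_prescriber: bool = False,
    dose_changed_in_window: bool = False,
) -> tuple[str, ...]:
    """Return the violated rule codes for one therapy (empty = eligible).

    Rules are evaluated independently so a therapy failing several rules
    reports all of them.  ``oral_other`` forms (e.g. oral solutions)
    count as oral and stay eligible as long as the daily dose is
    definite.
    """
    reasons: list[str] = []
    if regimen_type != "daily_fixed":
        reasons.append("NOT_DAILY")
    if form not in _vocab.ORAL_FORMS and form not in ("topical", "drops"):
        reasons.append("NOT_ORAL")
    if daily_dose is None or daily_dose <= 0:
        reasons.append("NO_DEFINITE_DOSE")
    if not has_pre_baseline_dispensing:
        reasons.append("NOT_REDEEMED_PRE_BASELINE")
    if self_dispensing_prescriber:
        reasons.append("SELF_DISPENSING")
    if dose_changed_in_window:
        reasons.append("DOSE_CHANGED")
    if atc_code.startswith(_vocab.ON_DEMAND_ATC_PREFIXES):
        reasons.append("ON_DEMAND_ATC")
    if form in ("topical", "drops"):
        reasons.append("FORM_EXCLUDED")
    return tuple(reasons)


def filter_therapies(
    regimen: pd.DataFrame,
    drug_master: pd.DataFrame,
    dispensing: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Apply the inclusion/exclusion rules to every therapy.

    Parameters
    ----------
    regimen, drug_master, dispensing
        Validated tables (see :mod:`polyadhere.io`).  Pre-baseline
        redemption is established from the dispensing ledger itself:
        at least one dispensing strictly before ``config.baseline_date``.

    Returns
    -------
    DataFrame with one row per therapy: ``patient_id``, ``product_id``,
    ``eligible`` (bool) and ``reasons`` ('|'-joined rule codes, empty
    string when eligible).
    """
    attrs = drug_master.set_index("product_id")[["atc_code", "form"]]
    pre_mask = [d < config.baseline_date for d in dispensing["dispense_date"]]
    pre_baseline = set(
        zip(dispensing.loc[pre_mask, "patient_id"], dispensing.loc[pre_mask, "product_id"])
    )

    rows = []
    for row in regimen.itertuples():
        product = attrs.loc[row.product_id]
        reasons = evaluate_therapy(
            regimen_type=row.regimen_type,
            form=product["form"],
            atc_code=product["atc_code"],
            daily_dose=row.daily_dose,
            has_pre_baseline_dispensing=(row.patient_id, row.product_id) in pre_baseline,
            self_dispensing_prescriber=bool(row.self_dispensing_prescriber),
            dose_changed_in_window=bool(row.dose_changed_in_window),
        )
        rows.append(
            {
                "patient_id": row.patient_id,
                "product_id": row.product_id,
                "eligible": not reasons,
                "reasons": "|".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "product_id", "eligible", "reasons"])


def eligible_patients(decisions: pd.DataFrame) -> set[str]:
    """Patients owning at least one eligible therapy (DPPR-eligible set)."""
    return set(decisions.loc[decisions["eligible"], "patient_id"])


def write_decisions(decisions: pd.DataFrame, path: str | Path) -> None:
    decisions.to_csv(path, index=False)


def read_decisions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "product_id": str}, keep_default_na=False)
    df["eligible"] = df["eligible"].astype(str).str.lower().isin(("true", "1"))
    return df
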