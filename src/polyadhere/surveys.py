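"""Subjective-adherence scoring and change classification.

Instruments and their strict non-adherence thresholds:

* VAS_AD — 0-100 visual analogue scale of self-reported adherence over
  the preceding two weeks; non-adherent iff < 100.
* 10-point Likert rating from the telephone interviews; non-adherent
  iff < 10.
* 8-item Morisky scale, German version (MMAS-8D), consumed as a
  precomputed 0-8 score in 0.25 steps; non-adherent iff < 6.00; banded
  as 8 = high, 6-7.75 = medium, < 6 = low adherence.
* Beliefs-about-Medicines Questionnaire (BMQ) necessity ("beliefs") and
  concerns subscales, analysed as item sums and their difference.

Patient-level change between two timepoints counts as improvement or
worsening only when it moves by strictly more than the threshold
(default 5 points on the 0-100 scale); a delta of exactly +-5 is stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "flag_subjective_nonadherence",
    "classify_mmas_band",
    "score_bmq",
    "classify_change",
    "ChangeClassification",
    "change_classification_table",
]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def flag_subjective_nonadherence(
    *,
    vas: float | None = None,
    likert: int | None = None,
    mmas: float | None = None,
) -> dict[str, bool]:
    """Per-instrument strict-threshold non-adherence flags.

    Missing instruments yield no flag (absent key).  At least one
    instrument must be present.
    """
    flags: dict[str, bool] = {}
    if not _is_missing(vas):
        if not 0 <= vas <= 100:
            raise ValueError(f"vas out of [0, 100]: {vas}")
        flags["vas"] = vas < 100
    if not _is_missing(likert):
        if not 1 <= likert <= 10:
            raise ValueError(f"likert out of [1, 10]: {likert}")
        flags["likert"] = likert < 10
    if not _is_missing(mmas):
        if not 0 <= mmas <= 8:
            raise ValueError(f"mmas out of [0, 8]: {mmas}")
        flags["mmas"] = mmas < 6.00
    if not flags:
        raise ValueError("no instrument present")
    return flags


def classify_mmas_band(mmas_score: float) -> str:
    """MMAS-8D adherence band: 8 high, 6-7.75 medium, <6 low."""
    if _is_missing(mmas_score) or not 0 <= mmas_score <= 8:
        raise ValueError(f"mmas_score out of [0, 8]: {mmas_score}")
    if mmas_score == 8:
        return "high"
    if mmas_score >= 6:
        return "medium"
    return "low"


def score_bmq(
    beliefs_items: Sequence[int | None] | None,
    concerns_items: Sequence[int | None] | None,
) -> tuple[int | None, int | None, int | None]:
    """BMQ subscale sums and their difference (beliefs - concerns).

    Any missing item voids all three outputs; no pro-rating or
    imputation is attempted.
    """
    def _sum(items):
        if items is None or any(_is_missing(x) for x in items):
            return None
        return int(sum(items))

    beliefs = _sum(beliefs_items)
    concerns = _sum(concerns_items)
    if beliefs is None or concerns is None:
        return (None, None, None)
    return (beliefs, concerns, beliefs - concerns)


@dataclass(frozen=True)
class ChangeClassification:
    patient_id: str
    delta: float | None
    category: str  # improved | worsened | stable | unknown


def classify_change(
    vas_before: float | None,
    vas_after: float | None,
    threshold: float = 5.0,
    patient_id: str = "",
) -> ChangeClassification:
    """Classify an adherence change of strictly more than ``threshold``.

    ``delta = after - before``; improved iff delta > threshold,
    worsened iff delta < -threshold, unknown if either value is
    missing.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if _is_missing(vas_before) or _is_missing(vas_after):
        return ChangeClassification(patient_id, None, "unknown")
    delta = vas_after - vas_before
    if delta > threshold:
        category = "improved"
    elif delta < -threshold:
        category = "worsened"
    else:
        category = "stable"
    return ChangeClassification(patient_id, delta, category)


def change_classification_table(
    surveys: pd.DataFrame,
    timepoint_before: str = "T0",
    timepoint_after: str = "T2",
    threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-patient change classification from the survey table.

    Returns one row per patient appearing at either timepoint with
    columns ``patient_id``, ``delta``, ``category``.
    """
    def _vas_at(tp: str) -> dict[str, float | None]:
        sub = surveys.loc[surveys["timepoint"] == tp, ["patient_id", "vas"]]
        return dict(zip(sub["patient_id"], sub["vas"]))

    before = _vas_at(timepoint_before)
    after = _vas_at(timepoint_after)
    rows = []
    for pid in sorted(set(before) | set(after)):
        cc = classify_change(before.get(pid), after.get(pid), threshold, patient_id=pid)
        rows.append({"patient_id": pid, "delta": cc.delta, "category": cc.category})
    return pd.DataFrame(rows, columns=["patient_id", "delta", "category"])
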