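"""Trial-level comparisons and design-stage calculations.

Frequencies are compared with Pearson's chi-square test (no continuity
correction by default), ordinal scales with the two-sided
Mann-Whitney-U test with midrank tie handling.  The design-stage
calculator sizes a two-arm comparison of means with the normal
approximation and inflates enrolment for anticipated dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _vocab

__all__ = [
    "ChiSquareResult",
    "RankSumResult",
    "SampleSizeSpec",
    "SampleSizeResult",
    "chi_square_test",
    "fisher_exact_test",
    "rank_sum_compare",
    "sample_size_two_means",
    "summarise_drps",
    "DRPSummary",
    "dropout_summary",
    "DropoutSummary",
    "change_contingency",
]


# -- contingency tables ---------------------------------------------------


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    pvalue: float


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return arr


def chi_square_test(table, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test on a contingency table.

    No continuity correction by default; pass ``correction=True`` for
    the Yates-corrected 2x2 variant.  A zero row or column margin makes
    the expected counts degenerate and raises.
    """
    arr = _as_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    res = stats.chi2_contingency(arr, correction=correction)
    return ChiSquareResult(
        statistic=float(res.statistic), dof=int(res.dof), pvalue=float(res.pvalue)
    )


def fisher_exact_test(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    pvalue: float


def rank_sum_compare(values_a: Sequence[float], values_b: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney-U comparison; ties handled by midranks."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankSumResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


# -- sample size ----------------------------------------------------------


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design inputs for a two-arm comparison of means."""

    alpha: float = 0.05
    power: float = 0.80
    detectable_difference: float = 5.0
    sd: float = 20.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.detectable_difference <= 0:
            raise ValueError("detectable_difference must be positive")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    n_per_group: int
    n_total_enrolment: int


def sample_size_two_means(spec: SampleSizeSpec) -> SampleSizeResult:
    """Two-sample normal-approximation sample size with dropout inflation.

    Completers per group::

        n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 (sd / difference)^2 )

    Enrolment inflates the two-group total by ``1 / (1 - dropout_rate)``
    and rounds up to the next multiple of 10 (recruitment is planned in
    round numbers of patients per site).
    """
    z_alpha = stats.norm.ppf(1 - spec.alpha / 2)
    z_beta = stats.norm.ppf(spec.power)
    n_exact = 2 * (z_alpha + z_beta) ** 2 * (spec.sd / spec.detectable_difference) ** 2
    n_per_group = math.ceil(n_exact)
    total_exact = 2 * n_per_group / (1 - spec.dropout_rate)
    n_total = int(math.ceil(total_exact / 10.0)) * 10
    return SampleSizeResult(n_per_group=n_per_group, n_total_enrolment=n_total)


# -- DRP tallies ----------------------------------------------------------


@dataclass(frozen=True)
class DRPSummary:
    n_drps: int
    n_patients: int
    rate_per_patient: float
    by_cause: pd.DataFrame
    by_intervention: pd.DataFrame
    by_urgency: pd.DataFrame
    by_status: pd.DataFrame
    by_acceptance: pd.DataFrame


def _tally(series: pd.Series, vocabulary: Mapping[str, int], total: int) -> pd.DataFrame:
    unknown = set(series) - set(vocabulary)
    if unknown:
        raise ValueError(f"unknown category value(s): {sorted(unknown)}")
    counts = series.value_counts()
    rows = [
        {
            "category": label,
            "n": int(counts.get(label, 0)),
            "percent": round(100.0 * counts.get(label, 0) / total, 1) if total else 0.0,
        }
        for label in vocabulary
    ]
    return pd.DataFrame(rows, columns=["category", "n", "percent"])


def summarise_drps(records: pd.DataFrame, n_patients: int) -> DRPSummary:
    """Tally drug-related problems by cause, intervention, urgency,
    status and acceptance, with the per-patient rate.

    ``records`` needs columns ``patient_id, status, urgency, cause,
    intervention, accepted`` drawn from the closed GSASA-derived
    vocabularies; percentages are reported to one decimal.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    total = len(records)

    def col(name: str) -> pd.Series:
        return records[name] if total else pd.Series([], dtype=str)

    return DRPSummary(
        n_drps=total,
        n_patients=n_patients,
        rate_per_patient=total / n_patients,
        by_cause=_tally(col("cause"), _vocab.DRP_CAUSES, total),
        by_intervention=_tally(col("intervention"), _vocab.DRP_INTERVENTIONS, total),
        by_urgency=_tally(col("urgency"), _vocab.DRP_URGENCY, total),
        by_status=_tally(col("status"), _vocab.DRP_STATUS, total),
        by_acceptance=_tally(col("accepted"), _vocab.DRP_ACCEPTED, total),
    )


# -- dropout --------------------------------------------------------------


@dataclass(frozen=True)
class DropoutSummary:
    enrolled: tuple[int, int]
    dropouts: tuple[int, int]
    arm_percentages: tuple[float, float]
    pooled_percentage: float
    #: None when the dropout/completer table is degenerate (e.g. no dropouts)
    chi_square: ChiSquareResult | None


def dropout_summary(
    enrolled: tuple[int, int], dropouts: tuple[int, int]
) -> DropoutSummary:
    """Per-arm and pooled dropout percentages plus the chi-square
    comparison of dropout counts between arms.

    ``enrolled`` and ``dropouts`` are (intervention, control) counts.
    The chi-square compares the dropout split across arms among all
    dropouts vs completers.
    """
    for n_enr, n_drop in zip(enrolled, dropouts):
        if n_drop > n_enr:
            raise ValueError("dropouts exceed enrolment")
    total_enrolled = sum(enrolled)
    total_drop = sum(dropouts)
    arm_pct = tuple(
        round(100.0 * d / n, 1) for d, n in zip(dropouts, enrolled)
    )
    pooled = round(100.0 * total_drop / total_enrolled, 1)
    table = [
        [dropouts[0], enrolled[0] - dropouts[0]],
        [dropouts[1], enrolled[1] - dropouts[1]],
    ]
    try:
        chi = chi_square_test(table)
    except ValueError:
        chi = None
    return DropoutSummary(
        enrolled=tuple(enrolled),
        dropouts=tuple(dropouts),
        arm_percentages=arm_pct,
        pooled_percentage=pooled,
        chi_square=chi,
    )


# -- change-classification contingency ------------------------------------


def change_contingency(
    classified: pd.DataFrame,
    allocation: pd.DataFrame,
    include_stable: bool = False,
) -> pd.DataFrame:
    """Arm x change-category contingency table from per-patient change
    classifications (see
    :func:`polyadhere.surveys.change_classification_table`).

    ``unknown`` classifications are dropped.  With ``include_stable``
    the table is 2x3 (improved/worsened/stable), otherwise 2x2.  Rows
    are arms (intervention, control).
    """
    merged = classified.merge(
        allocation[["patient_id", "arm"]], on="patient_id", how="inner"
    )
    categories = ["improved", "worsened"] + (["stable"] if include_stable else [])
    merged = merged[merged["category"].isin(categories)]
    table = pd.DataFrame(
        0, index=["intervention", "control"], columns=categories, dtype=int
    )
    for row in merged.itertuples():
        table.loc[row.arm, row.category] += 1
    return table
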