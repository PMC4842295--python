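"""Synthetic study generator with known ground-truth adherence.

Emulates the structure of a two-arm community-pharmacy adherence trial:
~50 pharmacies, patients on >=4 prescribed chronic medicines, a 200-day
pre-baseline refill history feeding the carry-over loop, a 196-day
observation window, 2x4 block allocation, configurable dropout, and
near-ceiling self-reported adherence.

Ground truth
------------
Each patient carries a ``true_availability`` parameter theta in (0, 1]:
the long-run fraction of days on which medication is in stock.  Refill
behaviour follows a stochastic stock-out model — each therapy alternates
covered runs (length = dispensed units / daily dose) and gap runs drawn
from a geometric distribution whose mean is tuned so the long-run
covered fraction equals theta.  This encodes exactly the estimand the
adherence engine must recover, so parameter-recovery tests close the
loop from generator to engine.

Determinism: all draws flow from a single integer seed; identical seeds
give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _vocab
from .config import StudyConfig
from .io import TableBundle, TABLE_SCHEMAS, write_tables

__all__ = [
    "ExclusionRates",
    "Cohort",
    "block_randomise",
    "generate_cohort",
    "simulate_dispensing",
    "simulate_surveys",
    "simulate_drps",
    "simulate_study",
    "write_study",
    "simulate_change_trial",
    "DRUG_CATALOGUE",
]


# -- drug catalogue -------------------------------------------------------

# (product_id, atc_code, package_size, form, dose options in units/day)
# Chronic oral products use the common long-term package sizes of 100 and
# 30 units; the excluded products exist to exercise the eligibility rules.
DRUG_CATALOGUE: list[tuple[str, str, int, str, tuple[str, ...]]] = [
    ("CHR01", "C07AB02", 100, "oral_solid", ("1/2", "1")),
    ("CHR02", "C10AA01", 100, "oral_solid", ("1",)),
    ("CHR03", "A02BC01", 30, "oral_solid", ("1",)),
    ("CHR04", "C09AA02", 100, "oral_solid", ("1", "2")),
    ("CHR05", "A10BA02", 100, "oral_solid", ("1", "2")),
    ("CHR06", "B01AC06", 30, "oral_solid", ("1",)),
    ("CHR07", "C03CA01", 30, "oral_solid", ("1/2", "1")),
    ("CHR08", "C08CA01", 100, "oral_solid", ("1",)),
    ("CHR09", "H03AA01", 100, "oral_solid", ("1",)),
    ("CHR10", "C09CA01", 100, "oral_solid", ("1",)),
    ("CHR11", "N06AB06", 30, "oral_solid", ("1",)),
    ("CHR12", "C01AA05", 30, "oral_other", ("1/2", "1")),
]

ON_DEMAND_CATALOGUE: list[tuple[str, str, int, str]] = [
    ("OND01", "N02BE01", 30, "oral_solid"),
    ("OND02", "M01AE01", 30, "oral_solid"),
    ("OND03", "N05BA12", 30, "oral_solid"),
    ("OND04", "A12CC30", 30, "oral_solid"),
]

NON_ORAL_CATALOGUE: list[tuple[str, str, int, str]] = [
    ("NOR01", "D07AC01", 30, "topical"),
    ("NOR02", "S01ED01", 10, "drops"),
    ("NOR03", "B01AB05", 10, "other"),
]


def _drug_master_frame() -> pd.DataFrame:
    rows = [
        {"product_id": p, "atc_code": a, "package_size": s, "form": f}
        for p, a, s, f, _ in DRUG_CATALOGUE
    ]
    rows += [
        {"product_id": p, "atc_code": a, "package_size": s, "form": f}
        for p, a, s, f in ON_DEMAND_CATALOGUE + NON_ORAL_CATALOGUE
    ]
    return pd.DataFrame(rows, columns=TABLE_SCHEMAS["drug_master"])


# -- configuration of the generator ---------------------------------------


@dataclass(frozen=True)
class ExclusionRates:
    """Per-therapy probabilities of exclusion-triggering attributes."""

    on_demand: float = 0.20
    non_oral: float = 0.10
    dose_changed: float = 0.12
    self_dispensing: float = 0.05

    def __post_init__(self) -> None:
        for name in ("on_demand", "non_oral", "dose_changed", "self_dispensing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.on_demand + self.non_oral > 1:
            raise ValueError("on_demand + non_oral must not exceed 1")


@dataclass
class Cohort:
    """Generated study population prior to dispensing simulation."""

    config: StudyConfig
    patients: pd.DataFrame
    regimen: pd.DataFrame
    drug_master: pd.DataFrame
    allocation: pd.DataFrame
    ground_truth: pd.DataFrame


# -- randomisation --------------------------------------------------------


def block_randomise(
    patient_ids_per_pharmacy: Mapping[str, Sequence[str]], seed: int
) -> pd.DataFrame:
    """2x4 permuted-block allocation, blocks of eight, four per arm.

    Each pharmacy consumes assignments from successive blocks of eight
    envelopes containing exactly four of each arm in seed-determined
    random order.  Partial final blocks are permitted (recruitment can
    stop mid-block), so within-pharmacy imbalance never exceeds four.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pharmacy_id in patient_ids_per_pharmacy:
        patients = list(patient_ids_per_pharmacy[pharmacy_id])
        if not patients:
            raise ValueError(f"empty patient list for pharmacy {pharmacy_id!r}")
        block: list[str] = []
        block_index = -1
        for patient_id in patients:
            if not block:
                block = ["intervention"] * 4 + ["control"] * 4
                block = [block[j] for j in rng.permutation(8)]
                block_index += 1
            arm = block.pop(0)
            position = 8 - len(block)
            rows.append(
                {
                    "patient_id": patient_id,
                    "pharmacy_id": pharmacy_id,
                    "arm": arm,
                    "block_index": block_index,
                    "position_in_block": position,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_SCHEMAS["allocation"])


# -- cohort ---------------------------------------------------------------


def _draw_availability(rng: np.random.Generator, distribution, size: int) -> np.ndarray:
    """Sample true availability in (0, 1] from a parametrised family."""
    kind, *params = distribution
    if kind == "fixed":
        (value,) = params
        if not 0 < value <= 1:
            raise ValueError("fixed availability must be in (0, 1]")
        theta = np.full(size, float(value))
    elif kind == "beta":
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError("beta parameters must be positive")
        theta = rng.beta(a, b, size=size)
    elif kind == "uniform":
        lo, hi = params
        if not 0 <= lo < hi <= 1:
            raise ValueError("uniform bounds must satisfy 0 <= lo < hi <= 1")
        theta = rng.uniform(lo, hi, size=size)
    else:
        raise ValueError(f"unknown availability distribution kind {kind!r}")
    return np.clip(theta, 0.01, 1.0)


def generate_cohort(
    config: StudyConfig,
    n_pharmacies: int = 50,
    n_patients: int = 450,
    adherence_distribution: tuple = ("beta", 14.0, 2.0),
    exclusion_rates: ExclusionRates = ExclusionRates(),
    dropout_rate: float = 0.17,
    mean_extra_therapies: float = 2.8,
) -> Cohort:
    """Generate pharmacies, patients, therapies and allocation.

    Every patient receives four core chronic daily therapies plus a
    Poisson number of additional therapies; exclusion-triggering
    attributes (on-demand ATC class, non-oral form, dose change during
    the window, self-dispensing prescriber) are assigned per therapy at
    the configured rates.  ``dropout_rate`` patients draw a dropout day
    uniform over the window.  Ground-truth availability is recorded per
    therapy.
    """
    if n_patients < 1 or n_pharmacies < 1:
        raise ValueError("need at least one patient and one pharmacy")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng([config.rng_seed, 0])

    theta = _draw_availability(rng, adherence_distribution, n_patients)
    pharmacy_ids = [f"PH{i:03d}" for i in range(1, n_pharmacies + 1)]
    chronic = list(DRUG_CATALOGUE)

    patients_rows = []
    regimen_rows = []
    truth_rows = []
    per_pharmacy: dict[str, list[str]] = {p: [] for p in pharmacy_ids}
    for i in range(n_patients):
        patient_id = f"PT{i + 1:04d}"
        pharmacy_id = pharmacy_ids[int(rng.integers(n_pharmacies))]
        per_pharmacy[pharmacy_id].append(patient_id)
        dropout_day = (
            int(rng.integers(0, config.window_days + 1))
            if rng.random() < dropout_rate
            else None
        )
        patients_rows.append(
            {
                "patient_id": patient_id,
                "pharmacy_id": pharmacy_id,
                "age": float(np.clip(rng.normal(67.2, 11.5), 19, 98).round(1)),
                "sex": "female" if rng.random() < 0.54 else "male",
                "lives_alone": bool(rng.random() < 0.34),
                "smoker": bool(rng.random() < 0.17),
                "dash4": float(np.clip(rng.normal(4.9, 1.9), 0, 16).round(1)),
                "true_availability": float(theta[i]),
                "dropout_day": dropout_day,
            }
        )

        n_therapies = 4 + int(rng.poisson(mean_extra_therapies))
        chronic_pool = [chronic[j] for j in rng.permutation(len(chronic))]
        ond_pool = [ON_DEMAND_CATALOGUE[j] for j in rng.permutation(len(ON_DEMAND_CATALOGUE))]
        nor_pool = [NON_ORAL_CATALOGUE[j] for j in rng.permutation(len(NON_ORAL_CATALOGUE))]
        for _ in range(n_therapies):
            u = rng.random()
            if u < exclusion_rates.on_demand and ond_pool:
                pid, _, _, _ = ond_pool.pop(0)
                row = {
                    "patient_id": patient_id,
                    "product_id": pid,
                    "daily_dose": None,
                    "regimen_type": "on_demand",
                    "dose_changed_in_window": False,
                    "self_dispensing_prescriber": False,
                    "redeemed_before_baseline": True,
                    "reported_change": "no_change",
                }
            elif u < exclusion_rates.on_demand + exclusion_rates.non_oral and nor_pool:
                pid, _, _, _ = nor_pool.pop(0)
                row = {
                    "patient_id": patient_id,
                    "product_id": pid,
                    "daily_dose": Fraction(1),
                    "regimen_type": "daily_fixed",
                    "dose_changed_in_window": False,
                    "self_dispensing_prescriber": False,
                    "redeemed_before_baseline": True,
                    "reported_change": "no_change",
                }
            elif chronic_pool:
                pid, _, _, _, doses = chronic_pool.pop(0)
                dose_changed = rng.random() < exclusion_rates.dose_changed
                row = {
                    "patient_id": patient_id,
                    "product_id": pid,
                    "daily_dose": Fraction(doses[int(rng.integers(len(doses)))]),
                    "regimen_type": "daily_fixed",
                    "dose_changed_in_window": dose_changed,
                    "self_dispensing_prescriber": rng.random()
                    < exclusion_rates.self_dispensing,
                    "redeemed_before_baseline": True,
                    "reported_change": "dosage_change" if dose_changed else "no_change",
                }
            else:
                continue
            regimen_rows.append(row)
            truth_rows.append(
                {
                    "patient_id": patient_id,
                    "product_id": row["product_id"],
                    "true_availability": float(theta[i]),
                }
            )

    recruited = {p: ids for p, ids in per_pharmacy.items() if ids}
    allocation = block_randomise(recruited, seed=int(rng.integers(2**31)))
    return Cohort(
        config=config,
        patients=pd.DataFrame(patients_rows),
        regimen=pd.DataFrame(regimen_rows, columns=TABLE_SCHEMAS["regimen"]),
        drug_master=_drug_master_frame(),
        allocation=allocation,
        ground_truth=pd.DataFrame(
            truth_rows, columns=["patient_id", "product_id", "true_availability"]
        ),
    )


# -- dispensing -----------------------------------------------------------


def _refill_days_daily(
    rng: np.random.Generator,
    theta: float,
    package_units: int,
    dose: Fraction,
    lookback: int,
    window: int,
    dropout_day: int | None,
) -> list[int]:
    """Refill days for one daily therapy under the stock-out model.

    Alternates covered runs (one package lasts ``package_units / dose``
    days, leftovers stack) with geometric gaps of mean
    ``L (1 - theta) / theta`` so the long-run covered fraction is
    theta.  The first refill falls in the look-back period, strictly
    before baseline, at a uniform phase within one mean cycle.
    """
    supply_days = float(Fraction(package_units) / dose)
    mean_gap = supply_days * (1.0 - theta) / theta
    cycle = supply_days + mean_gap
    first = -lookback + rng.uniform(0.0, min(cycle, float(lookback)))
    t = min(-1, int(math.floor(first)))

    days: list[int] = []
    stock = Fraction(0)
    while t < window:
        if dropout_day is not None and t > dropout_day:
            break
        days.append(t)
        stock += package_units
        run = int(stock / dose)
        stock -= run * dose
        gap = 0
        if theta < 1.0:
            gap = int(rng.geometric(1.0 / (1.0 + mean_gap))) - 1
        t = t + run + gap
    return days


def simulate_dispensing(cohort: Cohort, config: StudyConfig) -> pd.DataFrame:
    """Generate the dispensing ledger for a cohort.

    Daily-fixed therapies follow the stock-out model so the engine can
    recover ``true_availability``; on-demand therapies receive sporadic
    refills.  Every therapy has at least one pre-baseline dispensing;
    no dispensing occurs after a patient's dropout day; records are
    sorted by date.
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    sizes = dict(zip(cohort.drug_master["product_id"], cohort.drug_master["package_size"]))
    theta_by_patient = dict(
        zip(cohort.patients["patient_id"], cohort.patients["true_availability"])
    )
    dropout_by_patient = dict(
        zip(cohort.patients["patient_id"], cohort.patients["dropout_day"])
    )

    rows = []
    for row in cohort.regimen.itertuples():
        dropout_day = dropout_by_patient.get(row.patient_id)
        if dropout_day is not None and not pd.isna(dropout_day):
            dropout_day = int(dropout_day)
        else:
            dropout_day = None
        if row.regimen_type == "daily_fixed" and row.daily_dose is not None:
            days = _refill_days_daily(
                rng,
                theta_by_patient[row.patient_id],
                int(sizes[row.product_id]),
                row.daily_dose,
                config.lookback_days,
                config.window_days,
                dropout_day,
            )
        else:
            # sporadic on-demand refills: one guaranteed pre-baseline,
            # possibly one in-window
            days = [int(rng.integers(-config.lookback_days, 0))]
            if rng.random() < 0.5:
                d = int(rng.integers(0, config.window_days))
                if dropout_day is None or d <= dropout_day:
                    days.append(d)
        for d in days:
            rows.append(
                {
                    "patient_id": row.patient_id,
                    "product_id": row.product_id,
                    "dispense_date": config.date_for_day(d),
                    "packages": 1,
                }
            )
    df = pd.DataFrame(rows, columns=TABLE_SCHEMAS["dispensing"])
    return df.sort_values(
        ["dispense_date", "patient_id", "product_id"], kind="stable"
    ).reset_index(drop=True)


# -- surveys --------------------------------------------------------------


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_surveys(
    cohort: Cohort,
    config: StudyConfig,
    arm_effect: float = 0.0,
    baseline_mean: float = 96.0,
    baseline_sd: float = 8.0,
    within_sd: float = 4.0,
    missing_rate: float = 0.03,
) -> pd.DataFrame:
    """Simulate the survey table across T-0, T-2, T-16 and T-28.

    Each patient holds a latent adherence level drawn from a truncated
    normal (near-ceiling by default, mean 96 / SD 8 on the 0-100 VAS);
    observed VAS values add timepoint noise, shift the intervention arm
    by ``arm_effect`` at post-baseline timepoints, and clip to [0, 100].
    Interview timepoints (T-2, T-16) carry the Likert rating and BMQ
    items, T-16 additionally the MMAS score.  Responses after a
    patient's dropout day are missing, plus a small random missingness.
    """
    if not np.isfinite(arm_effect):
        raise ValueError("arm_effect must be finite")
    rng = np.random.default_rng([config.rng_seed, 2])
    arm = dict(zip(cohort.allocation["patient_id"], cohort.allocation["arm"]))
    n = len(cohort.patients)
    latent = _truncnorm(rng, baseline_mean, baseline_sd, 0, 100, n)

    rows = []
    for i, patient in enumerate(cohort.patients.itertuples()):
        dropout_day = patient.dropout_day
        dropout_day = None if dropout_day is None or pd.isna(dropout_day) else int(dropout_day)
        is_intervention = arm.get(patient.patient_id) == "intervention"
        for tp, day in config.timepoints.items():
            record: dict = {c: None for c in TABLE_SCHEMAS["surveys"]}
            record["patient_id"] = patient.patient_id
            record["timepoint"] = tp
            missing = (dropout_day is not None and day > dropout_day) or (
                rng.random() < missing_rate
            )
            if missing:
                rows.append(record)
                continue
            effect = arm_effect if (is_intervention and day > 0) else 0.0
            vas = float(np.clip(latent[i] + rng.normal(0.0, within_sd) + effect, 0, 100))
            record["vas"] = round(vas, 1)
            if tp in ("T2", "T16"):
                record["likert"] = int(np.clip(math.ceil(vas / 10), 1, 10))
                record.update(
                    {
                        f"bmq_beliefs_{k}": int(np.clip(round(rng.normal(4.1, 0.7)), 1, 5))
                        for k in range(1, 6)
                    }
                )
                record.update(
                    {
                        f"bmq_concerns_{k}": int(np.clip(round(rng.normal(2.0, 0.8)), 1, 5))
                        for k in range(1, 6)
                    }
                )
                if rng.random() < 0.02:  # occasional 'no answer' item
                    record[f"bmq_beliefs_{int(rng.integers(1, 6))}"] = None
            if tp == "T16":
                raw = 8 - (100 - vas) / 5 + rng.normal(0.0, 0.8)
                record["mmas_score"] = float(np.clip(round(raw / 0.25) * 0.25, 0, 8))
            record["unplanned_visits"] = int(rng.poisson(0.1))
            if tp == "T28":
                record["falls"] = int(rng.random() < 0.17)
            rows.append(record)
    return pd.DataFrame(rows, columns=TABLE_SCHEMAS["surveys"])


# -- drug-related problems ------------------------------------------------


def _sample_vocab(rng, vocabulary: Mapping[str, int], size: int) -> list[str]:
    labels = list(vocabulary)
    weights = np.array([vocabulary[k] for k in labels], dtype=float)
    weights /= weights.sum()
    return [labels[j] for j in rng.choice(len(labels), size=size, p=weights)]


def simulate_drps(
    cohort: Cohort, config: StudyConfig, rate_per_patient: float = 1.18
) -> pd.DataFrame:
    """Simulate medication-review DRP records for the intervention arm.

    Counts are Poisson per patient; categories are multinomial draws at
    the reference tally proportions of the adapted GSASA taxonomy.
    """
    rng = np.random.default_rng([config.rng_seed, 3])
    intervention = cohort.allocation.loc[
        cohort.allocation["arm"] == "intervention", "patient_id"
    ]
    counts = rng.poisson(rate_per_patient, size=len(intervention))
    patient_ids = np.repeat(list(intervention), counts)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "patient_id": patient_ids,
            "status": _sample_vocab(rng, _vocab.DRP_STATUS, total),
            "urgency": _sample_vocab(rng, _vocab.DRP_URGENCY, total),
            "cause": _sample_vocab(rng, _vocab.DRP_CAUSES, total),
            "intervention": _sample_vocab(rng, _vocab.DRP_INTERVENTIONS, total),
            "accepted": _sample_vocab(rng, _vocab.DRP_ACCEPTED, total),
        },
        columns=["patient_id", "status", "urgency", "cause", "intervention", "accepted"],
    )


# -- whole-study convenience ----------------------------------------------


def simulate_study(
    config: StudyConfig,
    n_pharmacies: int = 50,
    n_patients: int = 450,
    adherence_distribution: tuple = ("beta", 14.0, 2.0),
    exclusion_rates: ExclusionRates = ExclusionRates(),
    dropout_rate: float = 0.17,
    arm_effect: float = 0.0,
) -> tuple[Cohort, TableBundle, pd.DataFrame]:
    """Generate a complete synthetic study.

    Returns the cohort (with ground truth), the five-table bundle the
    IO layer consumes, and the DRP record table.
    """
    cohort = generate_cohort(
        config,
        n_pharmacies=n_pharmacies,
        n_patients=n_patients,
        adherence_distribution=adherence_distribution,
        exclusion_rates=exclusion_rates,
        dropout_rate=dropout_rate,
    )
    bundle = TableBundle(
        dispensing=simulate_dispensing(cohort, config),
        drug_master=cohort.drug_master,
        regimen=cohort.regimen,
        surveys=simulate_surveys(cohort, config, arm_effect=arm_effect),
        allocation=cohort.allocation,
    )
    drps = simulate_drps(cohort, config)
    return cohort, bundle, drps


def write_study(
    out_dir: str | Path,
    config: StudyConfig,
    **kwargs,
) -> tuple[Cohort, TableBundle, pd.DataFrame]:
    """Simulate a study and write all tables to *out_dir*.

    Writes the five interchange CSVs, the ground-truth file
    (``ground_truth.csv``, used only by tests), the DRP table and the
    config snapshot.
    """
    out_dir = Path(out_dir)
    cohort, bundle, drps = simulate_study(config, **kwargs)
    write_tables(bundle, out_dir)
    cohort.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    drps.to_csv(out_dir / "drp.csv", index=False)
    config.to_yaml(out_dir / "config.yaml")
    return cohort, bundle, drps


# -- fast survey-only trial replicates ------------------------------------


def simulate_change_trial(
    n_per_arm: int,
    arm_effect: float,
    seed: int,
    baseline_mean: float = 96.0,
    baseline_sd: float = 8.0,
    within_sd: float = 4.0,
    threshold: float = 5.0,
) -> np.ndarray:
    """One trial replicate reduced to the +-threshold change table.

    Vectorised survey-only simulation (same VAS model as
    :func:`simulate_surveys`) returning the 2x2 contingency table
    rows = (intervention, control), columns = (improved, worsened).
    Used for null-calibration studies over many replicates.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    latent = _truncnorm(rng, baseline_mean, baseline_sd, 0, 100, n)
    effect = np.where(np.arange(n) < n_per_arm, arm_effect, 0.0)
    vas0 = np.clip(latent + rng.normal(0.0, within_sd, n), 0, 100)
    vas2 = np.clip(latent + rng.normal(0.0, within_sd, n) + effect, 0, 100)
    delta = vas2 - vas0
    improved = delta > threshold
    worsened = delta < -threshold
    return np.array(
        [
            [int(improved[:n_per_arm].sum()), int(worsened[:n_per_arm].sum())],
            [int(improved[n_per_arm:].sum()), int(worsened[n_per_arm:].sum())],
        ]
    )
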