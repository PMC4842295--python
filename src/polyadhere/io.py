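"""Delimited-text interchange for the five study tables.

The pipeline consumes the kind of export a pharmacy clearing house can
produce: a dispensing ledger (date of refill, product identifier in the
pharmacode role, packages delivered), a drug master table carrying the ATC
code, package size in units and dose form for each product, the
patient-reported regimen, the survey responses, and the allocation list.

All tables are UTF-8 CSV with a header row, ISO-8601 dates, and strict
schemas: validation is total, so no malformed row ever reaches the
eligibility filter or the adherence engine.  Quantities stay exact
integers (units) and daily doses exact rationals until ratio computation.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import pandas as pd

from . import _vocab

__all__ = [
    "DispensingRecord",
    "DrugProduct",
    "TherapyEpisode",
    "TableBundle",
    "SchemaError",
    "MissingFileError",
    "MissingColumnError",
    "UnknownColumnError",
    "OrphanKeyError",
    "DateParseError",
    "InvalidValueError",
    "read_tables",
    "write_tables",
    "join_package_size",
    "parse_dose",
    "TABLE_SCHEMAS",
]


# -- errors ---------------------------------------------------------------


class SchemaError(ValueError):
    """Base class for table-contract violations."""


class MissingFileError(SchemaError):
    pass


class MissingColumnError(SchemaError):
    pass


class UnknownColumnError(SchemaError):
    pass


class OrphanKeyError(SchemaError):
    pass


class DateParseError(SchemaError):
    pass


class InvalidValueError(SchemaError):
    pass


# -- record types ---------------------------------------------------------


@dataclass(frozen=True)
class DispensingRecord:
    """One dated refill event of one product for one patient."""

    patient_id: str
    product_id: str
    dispense_date: dt.date
    packages: int

    def __post_init__(self) -> None:
        if self.packages < 1:
            raise InvalidValueError("packages must be >= 1")


@dataclass(frozen=True)
class DrugProduct:
    """Product master data: ATC code, package size in units, dose form."""

    product_id: str
    atc_code: str
    package_size: int
    form: str

    def __post_init__(self) -> None:
        if self.package_size < 1:
            raise InvalidValueError("package_size must be >= 1")
        if not _valid_atc(self.atc_code):
            raise InvalidValueError(f"malformed ATC code: {self.atc_code!r}")
        if self.form not in _vocab.FORMS:
            raise InvalidValueError(f"unknown dose form: {self.form!r}")


@dataclass(frozen=True)
class TherapyEpisode:
    """A patient-product therapy with regimen and change flags.

    The unit of MPR eligibility.  ``daily_dose`` is an exact rational
    (half-tablet doses are common) or ``None`` when no definite dose
    exists, e.g. for on-demand regimens.
    """

    patient_id: str
    product_id: str
    daily_dose: Fraction | None
    regimen_type: str
    dose_changed_in_window: bool = False
    self_dispensing_prescriber: bool = False
    redeemed_before_baseline: bool = True
    reported_change: str = "no_change"

    def __post_init__(self) -> None:
        if self.regimen_type not in _vocab.REGIMEN_TYPES:
            raise InvalidValueError(f"unknown regimen_type: {self.regimen_type!r}")
        if self.reported_change not in _vocab.REPORTED_CHANGES:
            raise InvalidValueError(f"unknown reported_change: {self.reported_change!r}")
        if self.regimen_type == "daily_fixed" and (
            self.daily_dose is None or self.daily_dose <= 0
        ):
            raise InvalidValueError("daily_fixed therapy requires daily_dose > 0")


# -- schemas --------------------------------------------------------------

_BMQ_BELIEFS = [f"bmq_beliefs_{i}" for i in range(1, 6)]
_BMQ_CONCERNS = [f"bmq_concerns_{i}" for i in range(1, 6)]

TABLE_SCHEMAS: dict[str, list[str]] = {
    "dispensing": ["patient_id", "product_id", "dispense_date", "packages"],
    "drug_master": ["product_id", "atc_code", "package_size", "form"],
    "regimen": [
        "patient_id",
        "product_id",
        "daily_dose",
        "regimen_type",
        "dose_changed_in_window",
        "self_dispensing_prescriber",
        "redeemed_before_baseline",
        "reported_change",
    ],
    "surveys": [
        "patient_id",
        "timepoint",
        "vas",
        "likert",
        *_BMQ_BELIEFS,
        *_BMQ_CONCERNS,
        "mmas_score",
        "unplanned_visits",
        "falls",
    ],
    "allocation": [
        "patient_id",
        "pharmacy_id",
        "arm",
        "block_index",
        "position_in_block",
    ],
}


@dataclass
class TableBundle:
    """The five validated study tables."""

    dispensing: pd.DataFrame
    drug_master: pd.DataFrame
    regimen: pd.DataFrame
    surveys: pd.DataFrame
    allocation: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}


# -- cell parsers ---------------------------------------------------------


def _valid_atc(code: str) -> bool:
    """ATC codes truncate at levels of 1, 3, 4, 5 or 7 characters."""
    if len(code) not in (1, 3, 4, 5, 7):
        return False
    if not (code[0].isalpha() and code[0].isupper()):
        return False
    if len(code) >= 3 and not code[1:3].isdigit():
        return False
    if len(code) >= 4 and not (code[3].isalpha() and code[3].isupper()):
        return False
    if len(code) >= 5 and not (code[4].isalpha() and code[4].isupper()):
        return False
    if len(code) == 7 and not code[5:7].isdigit():
        return False
    return True


def parse_dose(text: str) -> Fraction | None:
    """Parse a daily dose cell: decimal or ``p/q`` rational; empty -> None."""
    text = text.strip()
    if not text:
        return None
    try:
        dose = Fraction(text)
    except (ValueError, ZeroDivisionError) as exc:
        raise InvalidValueError(f"unparseable daily_dose {text!r}") from exc
    if dose <= 0:
        raise InvalidValueError(f"daily_dose must be positive, got {text!r}")
    return dose


def _parse_date(text: str, table: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise DateParseError(
            f"{table} row {row}: unparseable date {text!r}"
        ) from exc


def _parse_int(text: str, table: str, row: int, column: str, minimum: int | None = None) -> int:
    try:
        value = int(text)
    except ValueError as exc:
        raise InvalidValueError(
            f"{table} row {row}: column {column!r} not an integer: {text!r}"
        ) from exc
    if minimum is not None and value < minimum:
        raise InvalidValueError(
            f"{table} row {row}: column {column!r} must be >= {minimum}, got {value}"
        )
    return value


def _parse_bool(text: str, table: str, row: int, column: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise InvalidValueError(
        f"{table} row {row}: column {column!r} must be 'true' or 'false', got {text!r}"
    )


def _parse_opt_float(text: str, table: str, row: int, column: str) -> float | None:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise InvalidValueError(
            f"{table} row {row}: column {column!r} not numeric: {text!r}"
        ) from exc


def _parse_opt_int(text: str, table: str, row: int, column: str) -> int | None:
    if text == "":
        return None
    return _parse_int(text, table, row, column)


def _check_category(value: str, allowed, table: str, row: int, column: str) -> str:
    if value not in allowed:
        raise InvalidValueError(
            f"{table} row {row}: column {column!r} has unknown value {value!r}"
        )
    return value


# -- reading --------------------------------------------------------------


def _read_raw(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise MissingFileError(f"missing table file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = TABLE_SCHEMAS[name]
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing:
        raise MissingColumnError(f"{name}: missing columns {missing}")
    if unknown:
        raise UnknownColumnError(f"{name}: unknown columns {unknown}")
    return df[expected]


def _convert_dispensing(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["dispense_date"] = [
        _parse_date(v, "dispensing", i) for i, v in enumerate(df["dispense_date"])
    ]
    out["packages"] = [
        _parse_int(v, "dispensing", i, "packages", minimum=1)
        for i, v in enumerate(df["packages"])
    ]
    return out


def _convert_drug_master(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["package_size"] = [
        _parse_int(v, "drug_master", i, "package_size", minimum=1)
        for i, v in enumerate(df["package_size"])
    ]
    for i, (atc, form) in enumerate(zip(df["atc_code"], df["form"])):
        if not _valid_atc(atc):
            raise InvalidValueError(f"drug_master row {i}: malformed ATC code {atc!r}")
        _check_category(form, _vocab.FORMS, "drug_master", i, "form")
    if out["product_id"].duplicated().any():
        dupes = out.loc[out["product_id"].duplicated(), "product_id"].tolist()
        raise InvalidValueError(f"drug_master: duplicate product_id {dupes}")
    return out


def _convert_regimen(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    doses = []
    for i, row in df.iterrows():
        _check_category(row["regimen_type"], _vocab.REGIMEN_TYPES, "regimen", i, "regimen_type")
        _check_category(
            row["reported_change"], _vocab.REPORTED_CHANGES, "regimen", i, "reported_change"
        )
        try:
            doses.append(parse_dose(row["daily_dose"]))
        except InvalidValueError as exc:
            raise InvalidValueError(f"regimen row {i}: {exc}") from exc
    out["daily_dose"] = doses
    for col in ("dose_changed_in_window", "self_dispensing_prescriber", "redeemed_before_baseline"):
        out[col] = [_parse_bool(v, "regimen", i, col) for i, v in enumerate(df[col])]
    return out


#: numeric survey columns restricted to whole numbers
_SURVEY_INT_COLS = ("likert", *_BMQ_BELIEFS, *_BMQ_CONCERNS, "unplanned_visits", "falls")


def _convert_surveys(df: pd.DataFrame) -> pd.DataFrame:
    # missing responses are NaN; integer-valued columns are stored as
    # floats so missingness and values share one dtype
    out = df.copy()
    for i, tp in enumerate(df["timepoint"]):
        _check_category(tp, set(_vocab.TIMEPOINTS), "surveys", i, "timepoint")
    for col in ("vas", "mmas_score", *_SURVEY_INT_COLS):
        values = []
        for i, v in enumerate(df[col]):
            parsed = _parse_opt_float(v, "surveys", i, col)
            if parsed is not None and col in _SURVEY_INT_COLS and not float(parsed).is_integer():
                raise InvalidValueError(
                    f"surveys row {i}: column {col!r} must be a whole number, got {v!r}"
                )
            values.append(math.nan if parsed is None else float(parsed))
        out[col] = pd.Series(values, dtype=float)
    for i, (vas, likert, mmas) in enumerate(zip(out["vas"], out["likert"], out["mmas_score"])):
        if not math.isnan(vas) and not 0 <= vas <= 100:
            raise InvalidValueError(f"surveys row {i}: vas out of [0, 100]: {vas}")
        if not math.isnan(likert) and not 1 <= likert <= 10:
            raise InvalidValueError(f"surveys row {i}: likert out of [1, 10]: {likert}")
        if not math.isnan(mmas) and not 0 <= mmas <= 8:
            raise InvalidValueError(f"surveys row {i}: mmas_score out of [0, 8]: {mmas}")
    return out


def _convert_allocation(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for i, arm in enumerate(df["arm"]):
        _check_category(arm, _vocab.ARMS, "allocation", i, "arm")
    out["block_index"] = [
        _parse_int(v, "allocation", i, "block_index", minimum=0)
        for i, v in enumerate(df["block_index"])
    ]
    out["position_in_block"] = [
        _parse_int(v, "allocation", i, "position_in_block", minimum=1)
        for i, v in enumerate(df["position_in_block"])
    ]
    if (out["position_in_block"] > 8).any():
        raise InvalidValueError("allocation: position_in_block must be in 1..8")
    if out["patient_id"].duplicated().any():
        raise InvalidValueError("allocation: duplicate patient_id")
    return out


_CONVERTERS = {
    "dispensing": _convert_dispensing,
    "drug_master": _convert_drug_master,
    "regimen": _convert_regimen,
    "surveys": _convert_surveys,
    "allocation": _convert_allocation,
}


def _check_integrity(bundle: TableBundle) -> None:
    products = set(bundle.drug_master["product_id"])
    patients = set(bundle.allocation["patient_id"])

    orphan = set(bundle.dispensing["product_id"]) - products
    if orphan:
        raise OrphanKeyError(
            f"dispensing: product_id not in drug_master: {sorted(orphan)}"
        )
    orphan = set(bundle.regimen["product_id"]) - products
    if orphan:
        raise OrphanKeyError(f"regimen: product_id not in drug_master: {sorted(orphan)}")
    for name in ("dispensing", "regimen", "surveys"):
        orphan = set(getattr(bundle, name)["patient_id"]) - patients
        if orphan:
            raise OrphanKeyError(
                f"{name}: patient_id not in allocation: {sorted(orphan)}"
            )


def read_tables(directory: str | Path) -> TableBundle:
    """Read and validate the five study tables from *directory*.

    Raises a named :class:`SchemaError` subclass on the first violation:
    missing file, missing/unknown column, unparseable date or number,
    out-of-vocabulary category, or orphan foreign key.
    """
    directory = Path(directory)
    frames = {}
    for name in TABLE_SCHEMAS:
        raw = _read_raw(directory / f"{name}.csv", name)
        frames[name] = _CONVERTERS[name](raw)
    bundle = TableBundle(**frames)
    _check_integrity(bundle)
    return bundle


# -- writing --------------------------------------------------------------


def _serialise(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if name == "dispensing":
        out["dispense_date"] = [d.isoformat() for d in out["dispense_date"]]
    if name == "regimen":
        out["daily_dose"] = ["" if d is None else str(d) for d in out["daily_dose"]]
        for col in (
            "dose_changed_in_window",
            "self_dispensing_prescriber",
            "redeemed_before_baseline",
        ):
            out[col] = ["true" if v else "false" for v in out[col]]
    if name == "surveys":
        for col in out.columns:
            if col in ("patient_id", "timepoint"):
                continue

            def fmt(v, col=col):
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    return ""
                if col in _SURVEY_INT_COLS:
                    return str(int(v))
                return repr(float(v))

            out[col] = [fmt(v) for v in out[col]]
    return out


def write_tables(bundle: TableBundle, directory: str | Path) -> None:
    """Write the five tables as CSV into *directory* (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        _serialise(name, df[TABLE_SCHEMAS[name]]).to_csv(
            directory / f"{name}.csv", index=False
        )


# -- the package-size join ------------------------------------------------


def join_package_size(
    dispensing: pd.DataFrame, drug_master: pd.DataFrame
) -> pd.DataFrame:
    """Annotate dispensings with units dispensed (packages x package size).

    Mirrors the drug-index join that turns a package count into a tablet
    count.  Exact integer arithmetic; referential integrity must already
    hold (see :func:`read_tables`).
    """
    orphan = set(dispensing["product_id"]) - set(drug_master["product_id"])
    if orphan:
        raise OrphanKeyError(
            f"dispensing: product_id not in drug_master: {sorted(orphan)}"
        )
    merged = dispensing.merge(
        drug_master[["product_id", "package_size", "atc_code", "form"]],
        on="product_id",
        how="left",
        validate="many_to_one",
    )
    merged["units_dispensed"] = merged["packages"] * merged["package_size"]
    return merged
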