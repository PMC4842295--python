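"""Study configuration.

One :class:`StudyConfig` object carries the temporal layout of the trial
(baseline date, observation window, pre-baseline look-back, survey
timepoints) together with the analysis constants (non-adherence cut-off,
change-classification threshold, MPR capping).  Every module takes the
config explicitly; nothing reads global state.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["StudyConfig"]


@dataclass(frozen=True)
class StudyConfig:
    """Temporal layout and analysis constants of one study run.

    Parameters
    ----------
    baseline_date
        Calendar date of T-0.  Day 0 of the observation window.
    window_days
        Length of the observation window in days, half-open
        ``[T-0, T-0 + window_days)``.  Default 196 (28 weeks).
    lookback_days
        Length of the pre-baseline refill history used for carry-over,
        covering ``[T-0 - lookback_days, T-0)``.  Default 200.
    survey_offsets
        Day offsets from baseline of the three post-baseline survey
        timepoints (T-2, T-16, T-28 in weeks).  Strictly increasing and
        bounded by ``window_days``.
    nonadherence_cutoff
        Percentage below which a therapy (MPR) or patient (DPPR) is
        classified non-adherent; strict ``<`` comparison.  Default 80.
    change_threshold
        Points on the 0-100 adherence scale beyond which a change in
        self-reported adherence counts as improvement/worsening; strict
        "more than" comparison.  Default 5.
    mpr_cap_enabled
        Cap MPR at 100 % (default).  When disabled the uncapped
        supply-based ratio is reported instead.
    rng_seed
        Seed for every stochastic component downstream.
    """

    baseline_date: dt.date = dt.date(2013, 1, 1)
    window_days: int = 196
    lookback_days: int = 200
    survey_offsets: tuple[int, int, int] = (14, 112, 196)
    nonadherence_cutoff: float = 80.0
    change_threshold: float = 5.0
    mpr_cap_enabled: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.baseline_date, str):
            object.__setattr__(
                self, "baseline_date", dt.date.fromisoformat(self.baseline_date)
            )
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive")
        if not 0 < self.nonadherence_cutoff <= 100:
            raise ValueError("nonadherence_cutoff must be in (0, 100]")
        if self.change_threshold <= 0:
            raise ValueError("change_threshold must be positive")
        offsets = tuple(int(o) for o in self.survey_offsets)
        object.__setattr__(self, "survey_offsets", offsets)
        if len(offsets) != 3:
            raise ValueError("survey_offsets must hold three offsets (T-2, T-16, T-28)")
        if not all(a < b for a, b in zip(offsets, offsets[1:])):
            raise ValueError("survey_offsets must be strictly increasing")
        if offsets[-1] > self.window_days:
            raise ValueError("survey offsets must lie within the observation window")

    # -- timepoint helpers -------------------------------------------------

    @property
    def timepoints(self) -> dict[str, int]:
        """Mapping timepoint label -> day offset from baseline."""
        t2, t16, t28 = self.survey_offsets
        return {"T0": 0, "T2": t2, "T16": t16, "T28": t28}

    def day_offset(self, date: dt.date) -> int:
        """Days between *date* and baseline (negative = pre-baseline)."""
        return (date - self.baseline_date).days

    def date_for_day(self, day: int) -> dt.date:
        return self.baseline_date + dt.timedelta(days=int(day))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_date"] = self.baseline_date.isoformat()
        d["survey_offsets"] = list(self.survey_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
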