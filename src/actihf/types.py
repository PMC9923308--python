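"""Core domain containers for the accelerometry pipeline."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from . import constants
from .errors import IntegrityError

VISITS = ("baseline", "post_intervention", "final_followup")
WRISTS = ("left", "right")
CATEGORIES = ("inactive", "light", "mvpa")
DAY_TYPES = ("weekday", "weekend")
STRATA = ("all_days", "weekday", "weekend")
BOUTING_MODES = ("bouted", "unbouted")


@dataclass(frozen=True)
class ThresholdSet:
    """Wrist-specific ENMO intensity cut-points (mg).

    ``inactivity_cut`` separates inactive (< 1.5 METs) from light activity,
    ``mvpa_cut`` separates light from moderate-to-vigorous (>= 3.0 METs).
    """

    wrist: str
    inactivity_cut: float
    mvpa_cut: float

    def __post_init__(self) -> None:
        if self.wrist not in WRISTS:
            raise ValueError(f"unknown wrist {self.wrist!r}")
        if not (0.0 < self.inactivity_cut < self.mvpa_cut):
            raise ValueError("require 0 < inactivity_cut < mvpa_cut")


def threshold_profile(name: str) -> ThresholdSet:
    """Look up a named cut-point profile (``hf_left`` / ``hf_right``)."""
    wrist, lo, hi = constants.THRESHOLD_PROFILES[name]
    return ThresholdSet(wrist, lo, hi)


HF_LEFT = threshold_profile("hf_left")
HF_RIGHT = threshold_profile("hf_right")


@dataclass
class AccelStream:
    """A raw triaxial stream, accelerations in mg (1 g = 1000 mg)."""

    subject_id: str
    visit: str
    wrist: str
    sample_rate: float  # Hz
    t0: pd.Timestamp  # timezone-aware timestamp of the first sample
    samples: np.ndarray  # (n, 3) float array, mg

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if self.samples.shape[0] == 0:
            raise ValueError("empty stream")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.t0.tzinfo is None:
            raise ValueError("t0 must be timezone-aware")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.sample_rate

    def sample_offsets(self) -> np.ndarray:
        """Seconds of each sample since local midnight of the first day."""
        off0 = (self.t0 - self.t0.normalize()).total_seconds()
        return off0 + np.arange(self.n) / self.sample_rate

    def timestamps(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(np.arange(self.n) / self.sample_rate, unit="s")


@dataclass
class CalibrationResult:
    """Per-axis gain/offset fitted by autocalibration."""

    gain: np.ndarray  # (3,), dimensionless
    offset: np.ndarray  # (3,), mg
    n_stationary_epochs: int
    residual_error: float  # mg, mean | ||v|| - 1000 | over stationary points
    applied: bool


@dataclass
class EpochSeries:
    """Contiguous 5-s (by default) ENMO epochs with artifact/non-wear flags.

    Epoch boundaries are aligned to multiples of ``epoch_length`` counted
    from local midnight of the first day.
    """

    epoch_length: float  # seconds
    start: pd.Timestamp  # timezone-aware start of the first epoch
    enmo: np.ndarray  # mg, >= 0
    artifact: np.ndarray  # bool, same length
    nonwear: np.ndarray  # bool, same length
    subject_id: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        self.enmo = np.asarray(self.enmo, dtype=float)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        self.nonwear = np.asarray(self.nonwear, dtype=bool)
        if not (len(self.enmo) == len(self.artifact) == len(self.nonwear)):
            raise ValueError("flag arrays must match enmo length")
        if np.any(self.enmo < 0):
            raise ValueError("enmo values must be >= 0")

    @property
    def n(self) -> int:
        return len(self.enmo)

    @property
    def flagged(self) -> np.ndarray:
        """Epochs that do not count as wear (artifact or non-wear)."""
        return self.artifact | self.nonwear

    def start_offset_s(self) -> float:
        """Seconds from local midnight of the start day to the first epoch."""
        return (self.start - self.start.normalize()).total_seconds()

    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n) * self.epoch_length, unit="s"
        )

    def slice(self, i0: int, i1: int) -> "EpochSeries":
        return replace(
            self,
            start=self.start + pd.Timedelta(seconds=i0 * self.epoch_length),
            enmo=self.enmo[i0:i1].copy(),
            artifact=self.artifact[i0:i1].copy(),
            nonwear=self.nonwear[i0:i1].copy(),
        )


@dataclass
class ValidWeek:
    """The first run of 7 consecutive valid calendar days for a subject-visit."""

    subject_id: str
    visit: str
    days: Tuple[dt.date, ...]
    epochs: EpochSeries

    def __post_init__(self) -> None:
        if len(self.days) != 7:
            raise IntegrityError("a valid week must cover exactly 7 dates")
        for a, b in zip(self.days, self.days[1:]):
            if (b - a).days != 1:
                raise IntegrityError(f"dates not consecutive: {a} -> {b}")


@dataclass
class Bout:
    """A sustained period in one intensity category.

    Indices are inclusive epoch positions into the series the bout was
    detected on; the first and last epoch are always in-category and the
    in-category fraction is at least ``1 - allowance``.
    """

    category: str
    start_epoch: int
    end_epoch: int
    n_in_category: int

    @property
    def length(self) -> int:
        return self.end_epoch - self.start_epoch + 1


@dataclass
class DailySummary:
    """Per-calendar-day intensity minutes (bouted and unbouted) and wear time."""

    date: dt.date
    day_type: str  # weekday / weekend
    wear_min: float
    unbouted_min: Dict[str, float] = field(default_factory=dict)
    bouted_min: Dict[str, float] = field(default_factory=dict)


@dataclass
class SubjectVisitPA:
    """7-day physical-activity aggregates for one subject-visit.

    ``means`` maps (stratum, category, bouting) -> mean minutes/day, with
    stratum in {all_days, weekday, weekend}, category in
    {inactive, light, mvpa} and bouting in {bouted, unbouted}.
    """

    subject_id: str
    visit: str
    means: Dict[Tuple[str, str, str], float]
    weekly_mvpa_min: Dict[str, float]  # by bouting mode
    meets_guideline: Dict[str, bool]  # by bouting mode
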