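"""Quality classification, DST repair, exclusion filtering and hourly aggregation.

Weekly wrist-accelerometer recordings arrive as sequences of short epochs
(5 s by default) of mean acceleration magnitude in milli-gravity units (mg).
This module grades each week by completeness, repairs the two
daylight-saving-time (DST) transition defects by same-clock-hour imputation,
applies the cohort exclusion filters (high mean activity, low non-imputed
wear, withdrawn or age-ineligible participants), and averages each retained
week to a 168-value hourly profile aligned to a canonical Monday-start week.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOURS_PER_WEEK",
    "EpochSeries",
    "QualityCategory",
    "HourlyProfile",
    "ExclusionReport",
    "week_slots",
    "classify_quality",
    "repair_dst",
    "nonimputed_wear_hours",
    "apply_exclusions",
    "hourly_aggregate",
    "align_week",
    "preprocess_cohort",
    "round_half_up",
]

HOURS_PER_WEEK = 168

WEEKDAY_NAMES = ["monday", "tuesday", "wednesday", "thursday", "friday",
                 "saturday", "sunday"]

#: Default exclusion thresholds.
MEAN_EXCLUSION_MG = 100.0
MIN_WEAR_HOURS = 72.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), as printed tables do."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def week_slots(epoch_seconds: int) -> int:
    """Number of epoch slots in a complete 168-hour week (120,960 at 5 s)."""
    eph = epochs_per_hour(epoch_seconds)
    return HOURS_PER_WEEK * eph


def epochs_per_hour(epoch_seconds: int) -> int:
    if epoch_seconds <= 0 or 3600 % epoch_seconds:
        raise ValueError(f"epoch_seconds must divide 3600, got {epoch_seconds}")
    return 3600 // epoch_seconds


def parse_weekday(day: int | str) -> int:
    """Weekday as 0=Monday .. 6=Sunday from an index or a name."""
    if isinstance(day, str):
        try:
            return WEEKDAY_NAMES.index(day.strip().lower())
        except ValueError:
            raise ValueError(f"unknown weekday {day!r}") from None
    day = int(day)
    if not 0 <= day <= 6:
        raise ValueError(f"weekday index out of range: {day}")
    return day


class QualityCategory(enum.Enum):
    """Completeness grade of a weekly recording.

    The first five categories are usable; ``UNUSABLE`` weeks are dropped.
    """

    COMPLETE_PERFECT = "complete_perfect"
    COMPLETE_IMPUTED = "complete_imputed"
    RECOVERABLE = "recoverable"
    DST_SPRING = "dst_spring"
    DST_AUTUMN = "dst_autumn"
    UNUSABLE = "unusable"

    @property
    def usable(self) -> bool:
        return self is not QualityCategory.UNUSABLE


@dataclass
class EpochSeries:
    """One participant's week of epoch-level acceleration magnitudes.

    ``values`` uses NaN for blank (missing) epochs; ``imputed`` flags epochs
    whose values were filled in rather than measured (either upstream or by
    :func:`repair_dst`).
    """

    participant_id: str
    start_timestamp: pd.Timestamp
    epoch_seconds: int
    values: np.ndarray
    imputed: np.ndarray
    source_notes: str = ""

    def __post_init__(self) -> None:
        self.start_timestamp = pd.Timestamp(self.start_timestamp)
        self.values = np.asarray(self.values, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.imputed.shape != self.values.shape:
            raise ValueError("imputed flags must match values length")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("acceleration magnitudes must be >= 0 mg")
        epochs_per_hour(self.epoch_seconds)

    @property
    def epochs_per_hour(self) -> int:
        return epochs_per_hour(self.epoch_seconds)

    @property
    def n_slots(self) -> int:
        return self.values.size

    @property
    def start_day(self) -> int:
        """Weekday of the first epoch, 0=Monday."""
        return int(self.start_timestamp.dayofweek)

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def week_mean(self) -> float:
        """Mean magnitude over valid epochs (the 100 mg filter statistic)."""
        return float(np.nanmean(self.values))

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            participant_id=self.participant_id,
            start_timestamp=self.start_timestamp,
            epoch_seconds=self.epoch_seconds,
            values=self.values.copy(),
            imputed=self.imputed.copy(),
            source_notes=self.source_notes,
        )


@dataclass
class HourlyProfile:
    """168 hourly mean magnitudes, index 0 = Monday 00:00 once aligned."""

    participant_id: str
    hours: np.ndarray
    epochs_per_hour_used: np.ndarray
    quality: QualityCategory
    nonimputed_wear_hours: float
    start_day: int = 0
    aligned: bool = False

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        self.epochs_per_hour_used = np.asarray(self.epochs_per_hour_used, dtype=int)
        if self.hours.shape != (HOURS_PER_WEEK,):
            raise ValueError("an hourly profile must have exactly 168 values")
        if self.epochs_per_hour_used.shape != (HOURS_PER_WEEK,):
            raise ValueError("epochs_per_hour_used must have exactly 168 entries")
        if np.any(self.hours < 0):
            raise ValueError("hourly means must be >= 0 mg")


# ---------------------------------------------------------------------------
# Quality classification
# ---------------------------------------------------------------------------

def _longest_nan_run(values: np.ndarray) -> int:
    isnan = np.isnan(values)
    if not isnan.any():
        return 0
    padded = np.concatenate([[False], isnan, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def classify_quality(series: EpochSeries) -> QualityCategory:
    """Grade a weekly series by slot count, blanks and imputation flags.

    With 5 s epochs: a complete week has 120,960 slots; a spring-DST week
    (clocks forward, one blank hour, one extra trailing hour) has 121,680;
    an autumn-DST week (clocks back, one hour lost) has 120,240.
    """
    eph = series.epochs_per_hour
    full = HOURS_PER_WEEK * eph
    n = series.n_slots
    n_blank = int(np.isnan(series.values).sum())

    if n == full:
        if n_blank == 0:
            if series.imputed.any():
                return QualityCategory.COMPLETE_IMPUTED
            return QualityCategory.COMPLETE_PERFECT
        if n_blank == 1:
            return QualityCategory.RECOVERABLE
        return QualityCategory.UNUSABLE
    if n == full + eph:  # one extra hour of slots
        if _longest_nan_run(series.values) >= eph:
            return QualityCategory.DST_SPRING
        return QualityCategory.UNUSABLE
    if n == full - eph:
        return QualityCategory.DST_AUTUMN
    return QualityCategory.UNUSABLE


# ---------------------------------------------------------------------------
# DST repair
# ---------------------------------------------------------------------------

def _same_clock_hour_mean(values: np.ndarray, eph: int, hour_index: int,
                          n_hours: int) -> np.ndarray:
    """Epoch-wise mean of the same clock hour on the other days of the week."""
    clock = hour_index % 24
    others = [h for h in range(clock, n_hours, 24) if h != hour_index]
    stacked = np.stack([values[h * eph:(h + 1) * eph] for h in others])
    fill = np.nanmean(stacked, axis=0)
    if np.isnan(fill).any():
        raise ValueError("cannot impute: same clock hour blank on all other days")
    return fill


def repair_dst(series: EpochSeries, category: QualityCategory) -> EpochSeries:
    """Repair a DST-transition week to a complete 168-hour series.

    Spring (clocks forward): the blank hour is filled epoch-wise with the
    mean of the same clock hour on the other six days and the extra trailing
    hour is removed. Autumn (clocks back): the missing final hour is appended,
    filled the same way. Filled epochs carry imputation flags.
    """
    if category not in (QualityCategory.DST_SPRING, QualityCategory.DST_AUTUMN):
        raise ValueError(f"repair_dst requires a DST category, got {category}")
    eph = series.epochs_per_hour
    full = HOURS_PER_WEEK * eph

    if category is QualityCategory.DST_SPRING:
        if series.n_slots != full + eph:
            raise ValueError("spring-DST series must have 169 hours of slots")
        values = series.values[:full].copy()
        imputed = series.imputed[:full].copy()
        hourly_blank = np.isnan(values).reshape(HOURS_PER_WEEK, eph).all(axis=1)
        blank_hours = np.flatnonzero(hourly_blank)
        if blank_hours.size == 0:
            raise ValueError("spring-DST series has no fully blank hour")
        h = int(blank_hours[0])
        values[h * eph:(h + 1) * eph] = _same_clock_hour_mean(
            series.values[:full], eph, h, HOURS_PER_WEEK)
        imputed[h * eph:(h + 1) * eph] = True
        notes = (series.source_notes + "; " if series.source_notes else "") + \
            f"spring DST: hour {h} imputed from same clock hour, trailing hour dropped"
    else:
        if series.n_slots != full - eph:
            raise ValueError("autumn-DST series must have 167 hours of slots")
        fill = _same_clock_hour_mean(series.values, eph, HOURS_PER_WEEK - 1,
                                     HOURS_PER_WEEK - 1)
        values = np.concatenate([series.values, fill])
        imputed = np.concatenate([series.imputed, np.ones(eph, dtype=bool)])
        notes = (series.source_notes + "; " if series.source_notes else "") + \
            "autumn DST: final hour imputed from same clock hour"

    return EpochSeries(
        participant_id=series.participant_id,
        start_timestamp=series.start_timestamp,
        epoch_seconds=series.epoch_seconds,
        values=values,
        imputed=imputed,
        source_notes=notes,
    )


def nonimputed_wear_hours(series: EpochSeries) -> float:
    """Hours covered by valid epochs that were measured, not imputed."""
    valid = series.valid_mask() & ~series.imputed
    return float(valid.sum() * series.epoch_seconds) / 3600.0


# ---------------------------------------------------------------------------
# Hourly aggregation and week alignment
# ---------------------------------------------------------------------------

def hourly_aggregate(series: EpochSeries,
                     quality: QualityCategory | None = None) -> HourlyProfile:
    """Average a complete (repaired) week to 168 hourly means.

    Blank epochs are excluded from the mean and from the per-hour count; a
    recoverable week therefore has exactly one hour averaged over one fewer
    epoch (719 rather than 720 at 5 s resolution).
    """
    eph = series.epochs_per_hour
    if series.n_slots != HOURS_PER_WEEK * eph:
        raise ValueError(
            "hourly_aggregate requires a complete week "
            f"({HOURS_PER_WEEK * eph} slots), got {series.n_slots}")
    grid = series.values.reshape(HOURS_PER_WEEK, eph)
    counts = (~np.isnan(grid)).sum(axis=1)
    if (counts == 0).any():
        raise ValueError("an hour with no valid epochs cannot be averaged")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(grid, axis=1)
    return HourlyProfile(
        participant_id=series.participant_id,
        hours=means,
        epochs_per_hour_used=counts,
        quality=quality if quality is not None else classify_quality(series),
        nonimputed_wear_hours=nonimputed_wear_hours(series),
        start_day=series.start_day,
        aligned=False,
    )


def align_week(profile: HourlyProfile,
               start_day: int | str | None = None) -> HourlyProfile:
    """Rotate a profile so index 0 is Monday 00:00.

    A recording starting on Wednesday is rotated by 48 hours. Aligning an
    already-aligned profile is the identity.
    """
    if profile.aligned:
        return profile
    day = parse_weekday(profile.start_day if start_day is None else start_day)
    return HourlyProfile(
        participant_id=profile.participant_id,
        hours=np.roll(profile.hours, day * 24),
        epochs_per_hour_used=np.roll(profile.epochs_per_hour_used, day * 24),
        quality=profile.quality,
        nonimputed_wear_hours=profile.nonimputed_wear_hours,
        start_day=day,
        aligned=True,
    )


# ---------------------------------------------------------------------------
# Exclusion funnel
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Counts at every stage of the selection funnel, with reason codes.

    The funnel runs: supplied -> remove withdrawn and age-ineligible
    participants -> remove unusable-quality weeks -> remove weeks with mean
    activity at or above the threshold or under the minimum non-imputed wear
    (the last two applied jointly, both reasons recorded).
    """

    n_supplied: int
    n_withdrawn: int = 0
    n_age_ineligible: int = 0
    category_counts: dict = field(default_factory=dict)
    n_mean_ge_threshold: int = 0
    n_wear_lt_threshold: int = 0
    n_suitability_excluded: int = 0
    n_retained: int = 0
    mean_threshold_mg: float = MEAN_EXCLUSION_MG
    min_wear_hours: float = MIN_WEAR_HOURS
    reasons: dict = field(default_factory=dict)

    @property
    def n_available(self) -> int:
        return self.n_supplied - self.n_withdrawn - self.n_age_ineligible

    @property
    def n_usable(self) -> int:
        return self.n_available - self.category_counts.get(
            QualityCategory.UNUSABLE.value, 0)

    def pct_available_of_supplied(self) -> float:
        return 100.0 * self.n_available / self.n_supplied

    def pct_usable_of_available(self) -> float:
        return 100.0 * self.n_usable / self.n_available

    def pct_retained_of_supplied(self) -> float:
        return 100.0 * self.n_retained / self.n_supplied

    def check_conservation(self) -> None:
        n_unusable = self.category_counts.get(QualityCategory.UNUSABLE.value, 0)
        total = (self.n_withdrawn + self.n_age_ineligible + n_unusable
                 + self.n_suitability_excluded + self.n_retained)
        if total != self.n_supplied:
            raise AssertionError(
                f"funnel does not conserve counts: {total} != {self.n_supplied}")

    def to_json(self) -> str:
        payload = {
            "n_supplied": self.n_supplied,
            "n_withdrawn": self.n_withdrawn,
            "n_age_ineligible": self.n_age_ineligible,
            "n_available": self.n_available,
            "category_counts": dict(self.category_counts),
            "n_usable": self.n_usable,
            "n_mean_ge_threshold": self.n_mean_ge_threshold,
            "n_wear_lt_threshold": self.n_wear_lt_threshold,
            "n_suitability_excluded": self.n_suitability_excluded,
            "n_retained": self.n_retained,
            "mean_threshold_mg": self.mean_threshold_mg,
            "min_wear_hours": self.min_wear_hours,
            "pct_available_of_supplied": round_half_up(
                self.pct_available_of_supplied(), 1),
            "pct_usable_of_available": round_half_up(
                self.pct_usable_of_available(), 1),
            "pct_retained_of_supplied": round_half_up(
                self.pct_retained_of_supplied(), 1),
            "reasons": {k: list(v) for k, v in self.reasons.items()},
        }
        return json.dumps(payload, indent=2)

    def summary(self) -> str:
        lines = [
            f"supplied: {self.n_supplied}",
            f"withdrawn: {self.n_withdrawn}",
            f"age ineligible: {self.n_age_ineligible}",
            f"available: {self.n_available} "
            f"({round_half_up(self.pct_available_of_supplied(), 1)}% of supplied)",
        ]
        for cat, count in sorted(self.category_counts.items()):
            lines.append(f"  quality {cat}: {count}")
        lines += [
            f"usable: {self.n_usable} "
            f"({round_half_up(self.pct_usable_of_available(), 1)}% of available)",
            f"mean >= {self.mean_threshold_mg:g} mg: {self.n_mean_ge_threshold}",
            f"non-imputed wear < {self.min_wear_hours:g} h: {self.n_wear_lt_threshold}",
            f"retained: {self.n_retained} "
            f"({round_half_up(self.pct_retained_of_supplied(), 1)}% of supplied)",
        ]
        return "\n".join(lines)


class _FunnelState:
    """Incremental funnel bookkeeping shared by the list and streaming APIs."""

    def __init__(self, metadata: pd.DataFrame | None,
                 mean_threshold_mg: float, min_wear_hours: float) -> None:
        self.meta: Mapping[str, pd.Series] = {}
        if metadata is not None:
            md = metadata.set_index("participant_id") \
                if "participant_id" in metadata.columns else metadata
            self.meta = {str(pid): row for pid, row in md.iterrows()}
        self.mean_threshold_mg = mean_threshold_mg
        self.min_wear_hours = min_wear_hours
        self.reasons: dict[str, list[str]] = {}
        self.category_counts: dict[str, int] = {}
        self.n_seen = 0
        self.n_withdrawn = self.n_age = 0
        self.n_mean = self.n_wear = self.n_suit = self.n_retained = 0

    @staticmethod
    def _flag(row: pd.Series | None, key: str) -> bool:
        if row is None or key not in row:
            return False
        return bool(row[key])

    def admit(self, series: EpochSeries, quality: QualityCategory) -> bool:
        """Record one participant; True if the series survives the funnel."""
        self.n_seen += 1
        pid = series.participant_id
        row = self.meta.get(pid)
        if self._flag(row, "withdrawn"):
            self.n_withdrawn += 1
            self.reasons[pid] = ["withdrawn"]
            return False
        age_bad = self._flag(row, "age_ineligible")
        if not age_bad and row is not None and "age" in row and pd.notna(row["age"]):
            age_bad = not (40 <= float(row["age"]) <= 69)
        if age_bad:
            self.n_age += 1
            self.reasons[pid] = ["age_ineligible"]
            return False
        self.category_counts[quality.value] = \
            self.category_counts.get(quality.value, 0) + 1
        if not quality.usable:
            self.reasons[pid] = ["unusable_quality"]
            return False
        codes = []
        if series.week_mean() >= self.mean_threshold_mg:
            codes.append("mean_ge_threshold")
            self.n_mean += 1
        if nonimputed_wear_hours(series) < self.min_wear_hours:
            codes.append("wear_lt_threshold")
            self.n_wear += 1
        if codes:
            self.n_suit += 1
            self.reasons[pid] = codes
            return False
        self.n_retained += 1
        return True

    def report(self) -> ExclusionReport:
        report = ExclusionReport(
            n_supplied=self.n_seen,
            n_withdrawn=self.n_withdrawn,
            n_age_ineligible=self.n_age,
            category_counts=self.category_counts,
            n_mean_ge_threshold=self.n_mean,
            n_wear_lt_threshold=self.n_wear,
            n_suitability_excluded=self.n_suit,
            n_retained=self.n_retained,
            mean_threshold_mg=self.mean_threshold_mg,
            min_wear_hours=self.min_wear_hours,
            reasons=self.reasons,
        )
        report.check_conservation()
        return report


def apply_exclusions(
    cohort: Sequence[EpochSeries],
    metadata: pd.DataFrame | None = None,
    qualities: Sequence[QualityCategory] | None = None,
    mean_threshold_mg: float = MEAN_EXCLUSION_MG,
    min_wear_hours: float = MIN_WEAR_HOURS,
) -> tuple[list[EpochSeries], ExclusionReport]:
    """Run the selection funnel on classified (and DST-repaired) series.

    ``metadata`` may carry ``withdrawn`` and ``age_ineligible`` boolean
    columns (or an ``age`` column; eligibility is 40-69 at baseline) indexed
    by ``participant_id``. ``qualities`` are the pre-repair categories; when
    omitted each series is classified in place. The mean-activity and
    wear-time filters are applied jointly and both reasons recorded.
    """
    if qualities is None:
        qualities = [classify_quality(s) for s in cohort]
    if len(qualities) != len(cohort):
        raise ValueError("one quality category required per series")

    state = _FunnelState(metadata, mean_threshold_mg, min_wear_hours)
    retained = [series for series, quality in zip(cohort, qualities)
                if state.admit(series, quality)]
    return retained, state.report()


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def preprocess_cohort(
    cohort: Iterable[EpochSeries],
    metadata: pd.DataFrame | None = None,
    mean_threshold_mg: float = MEAN_EXCLUSION_MG,
    min_wear_hours: float = MIN_WEAR_HOURS,
    align: bool = True,
) -> tuple[list[HourlyProfile], ExclusionReport]:
    """Classify, repair, filter and aggregate a cohort in one streaming pass.

    Accepts any iterable of series (a generator keeps memory flat for
    full-resolution cohorts: each week is reduced to its 168-hour profile
    before the next is generated) and returns aligned profiles for the
    retained participants plus the reconciled exclusion report.
    """
    state = _FunnelState(metadata, mean_threshold_mg, min_wear_hours)
    profiles: list[HourlyProfile] = []
    for series in cohort:
        quality = classify_quality(series)
        if quality in (QualityCategory.DST_SPRING, QualityCategory.DST_AUTUMN):
            series = repair_dst(series, quality)
        if state.admit(series, quality):
            profile = hourly_aggregate(series, quality)
            if align:
                profile = align_week(profile)
            profiles.append(profile)
    return profiles, state.report()
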