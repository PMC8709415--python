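"""Synthetic weekly accelerometer cohorts with known cluster structure.

Nine archetypal diurnal/weekly activity patterns (from a commuting
"active_9to5" shape down to a flat "inactive" shape) are expressed as
168-hour mg templates: a resting base level plus Gaussian bumps per day,
with an optional weekend multiplier. Participants are simulated as epoch
series around a template with truncated, heteroscedastic Gaussian noise,
then optionally degraded with the completeness scenarios seen in real
cohorts: a single trailing blank epoch, spring/autumn daylight-saving
transition weeks, upstream-imputed blocks, scattered unusable gaps,
high-mean outliers and low-wear participants.

All randomness flows from a single integer seed through spawned
``numpy.random`` generators, so a fixed seed reproduces the cohort and its
truth table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    HOURS_PER_WEEK,
    EpochSeries,
    epochs_per_hour,
    parse_weekday,
)

__all__ = [
    "ARCHETYPE_NAMES",
    "ArchetypeSpec",
    "CohortConfig",
    "default_archetypes",
    "make_archetype_template",
    "simulate_participant",
    "inject_missingness",
    "simulate_cohort",
    "iter_cohort",
]

ARCHETYPE_NAMES = [
    "active_9to5",
    "active",
    "morning_movers",
    "get_up_and_active",
    "live_for_weekend",
    "moderates",
    "leisurely_9to5",
    "sedate",
    "inactive",
]

MISSINGNESS_SCENARIOS = [
    "none", "trailing_blank", "spring_dst", "autumn_dst",
    "imputed_blocks", "random_gaps",
]

#: Scenario mix for usable weeks, proportional to the completeness grades
#: observed in large wrist-accelerometer cohorts (roughly 24% pristine,
#: 49% upstream-imputed, 23% one trailing blank, 1% spring and 2% autumn
#: DST weeks).
DEFAULT_MISSINGNESS_MIX = {
    "none": 0.239,
    "imputed_blocks": 0.493,
    "trailing_blank": 0.234,
    "spring_dst": 0.012,
    "autumn_dst": 0.022,
    "random_gaps": 0.0,
}


@dataclass
class ArchetypeSpec:
    """Parametric description of one weekly activity pattern.

    ``peak_times`` entries are ``(day, hour, amplitude_mg, width_hours)``
    Gaussian bumps added to the resting ``base_level``;
    ``weekend_modifier`` multiplies the above-base signal on Saturday and
    Sunday.
    """

    name: str
    base_level: float
    peak_times: list = field(default_factory=list)
    weekend_modifier: float = 1.0

    def __post_init__(self) -> None:
        if self.base_level < 0:
            raise ValueError("base_level must be >= 0 mg")
        for day, hour, amp, width in self.peak_times:
            parse_weekday(day)
            if amp < 0:
                raise ValueError("peak amplitudes must be >= 0 mg")
            if width <= 0:
                raise ValueError("peak widths must be > 0 h")
            if not 0 <= hour < 24:
                raise ValueError("peak hours must lie in [0, 24)")


def _daily(hour: float, amp: float, width: float,
           days: Sequence[int]) -> list[tuple[int, float, float, float]]:
    return [(d, hour, amp, width) for d in days]


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """The nine built-in archetypes, in mg on an hourly grid.

    Amplitudes are chosen so hourly means sit in the range seen on wrist
    ENMO data (night base 6-12 mg, daytime 15-70 mg) and the shapes follow
    their names: commuting spikes around 08:00 and 17:30 for the 9-to-5
    patterns, a single morning burst for morning movers, weekend-only peaks
    for the weekend pattern, and a flat low profile for the inactive group.
    """
    wd, we, all_days = range(5), (5, 6), range(7)
    return {
        "active_9to5": ArchetypeSpec(
            "active_9to5", 12.0,
            _daily(8.0, 45.0, 1.2, wd) + _daily(17.5, 40.0, 1.5, wd)
            + _daily(13.0, 25.0, 4.0, wd)
            + [(5, 10.5, 42.0, 2.0), (6, 10.0, 40.0, 2.0),
               (5, 14.5, 18.0, 3.0), (6, 14.5, 16.0, 3.0)]),
        "active": ArchetypeSpec(
            "active", 12.0,
            _daily(8.0, 40.0, 1.5, wd) + _daily(13.5, 38.0, 4.5, wd)
            + [(5, 11.0, 38.0, 3.0), (6, 11.0, 36.0, 3.0)]),
        "morning_movers": ArchetypeSpec(
            "morning_movers", 10.0,
            _daily(8.0, 38.0, 1.8, all_days) + _daily(11.5, 12.0, 2.5, all_days)),
        "get_up_and_active": ArchetypeSpec(
            "get_up_and_active", 10.0,
            _daily(7.5, 32.0, 1.5, all_days) + _daily(14.0, 22.0, 4.0, all_days)),
        "live_for_weekend": ArchetypeSpec(
            "live_for_weekend", 10.0,
            _daily(13.0, 18.0, 4.5, wd)
            + [(5, 11.5, 30.0, 2.5), (6, 9.5, 38.0, 2.0)],
            weekend_modifier=1.2),
        "moderates": ArchetypeSpec(
            "moderates", 10.0, _daily(13.0, 22.0, 5.0, all_days)),
        "leisurely_9to5": ArchetypeSpec(
            "leisurely_9to5", 9.0,
            _daily(8.0, 22.0, 1.2, wd) + _daily(17.5, 20.0, 1.5, wd)
            + _daily(13.0, 13.0, 4.0, wd)
            + [(5, 12.0, 10.0, 3.0), (6, 12.0, 10.0, 3.0)]),
        "sedate": ArchetypeSpec(
            "sedate", 8.0,
            _daily(9.0, 14.0, 2.0, all_days) + _daily(12.0, 7.0, 3.0, all_days)),
        "inactive": ArchetypeSpec(
            "inactive", 6.0, _daily(13.0, 6.0, 5.5, all_days)),
    }


def make_archetype_template(spec: ArchetypeSpec | str) -> np.ndarray:
    """Evaluate an archetype to its 168-hour template (index 0 = Monday 00:00)."""
    if isinstance(spec, str):
        archetypes = default_archetypes()
        if spec not in archetypes:
            raise ValueError(
                f"unknown archetype {spec!r}; expected one of {ARCHETYPE_NAMES}")
        spec = archetypes[spec]
    template = np.full(HOURS_PER_WEEK, float(spec.base_level))
    hours = np.arange(24, dtype=float)
    for day, hour, amp, width in spec.peak_times:
        day = parse_weekday(day)
        bump = amp * np.exp(-0.5 * ((hours - hour) / width) ** 2)
        template[day * 24:(day + 1) * 24] += bump
    if spec.weekend_modifier != 1.0:
        for day in (5, 6):
            seg = slice(day * 24, (day + 1) * 24)
            template[seg] = spec.base_level + \
                spec.weekend_modifier * (template[seg] - spec.base_level)
    return np.clip(template, 0.0, None)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults give 100 participants per archetype (900 total) at the native
    5 s epoch resolution with moderate epoch-level noise, plus a handful of
    high-mean outliers and low-wear participants destined for exclusion.
    """

    n_per_archetype: int = 100
    epoch_seconds: int = 5
    noise_sd: float = 30.0
    seed: int = 0
    missingness_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS_MIX))
    n_outliers_high_mean: int = 3
    n_low_wear: int = 5
    start_day_distribution: tuple = (1 / 7,) * 7
    archetypes: dict = field(default_factory=default_archetypes)
    outlier_level_mg: float = 150.0
    low_wear_hours_flagged: int = 100

    def __post_init__(self) -> None:
        if self.n_per_archetype < 0 or self.n_outliers_high_mean < 0 \
                or self.n_low_wear < 0:
            raise ValueError("participant counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        epochs_per_hour(self.epoch_seconds)
        unknown = set(self.missingness_mix) - set(MISSINGNESS_SCENARIOS)
        if unknown:
            raise ValueError(f"unknown missingness scenarios: {sorted(unknown)}")
        total = sum(self.missingness_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"missingness proportions must sum to 1, got {total}")
        if not np.isclose(sum(self.start_day_distribution), 1.0, atol=1e-6):
            raise ValueError("start_day_distribution must sum to 1")


# ---------------------------------------------------------------------------
# Participant simulation
# ---------------------------------------------------------------------------

def _recording_template(template: np.ndarray, start_day: int) -> np.ndarray:
    """Template reordered to recording time for a week starting on start_day."""
    idx = (start_day * 24 + np.arange(HOURS_PER_WEEK)) % HOURS_PER_WEEK
    return template[idx]


def simulate_participant(
    template: np.ndarray,
    config: CohortConfig,
    participant_seed: int,
    start_day: int | str = 0,
    participant_id: str | None = None,
) -> EpochSeries:
    """Simulate one complete week of epochs around an hourly template.

    Epoch noise is Gaussian, truncated at 0 mg, with a standard deviation
    scaled by the local activity level (more active hours are noisier):
    ``sd = noise_sd * (0.5 + level / mean(template))``. A zero-noise series
    re-aggregates to the template exactly.
    """
    template = np.asarray(template, dtype=float)
    if template.shape != (HOURS_PER_WEEK,):
        raise ValueError("template must have exactly 168 hourly values")
    start_day = parse_weekday(start_day)
    eph = epochs_per_hour(config.epoch_seconds)
    rec = _recording_template(template, start_day)
    hourly_means = np.repeat(rec, eph)
    if config.noise_sd > 0:
        rng = np.random.default_rng(participant_seed)
        scale = config.noise_sd * (0.5 + hourly_means / max(template.mean(), 1e-9))
        values = np.clip(rng.normal(hourly_means, scale), 0.0, None)
    else:
        values = hourly_means.copy()
    # Monday of the week containing the start; recordings begin at midnight.
    start_ts = pd.Timestamp("2015-06-01") + pd.Timedelta(days=start_day)
    return EpochSeries(
        participant_id=participant_id or f"syn('{participant_seed}')",
        start_timestamp=start_ts,
        epoch_seconds=config.epoch_seconds,
        values=values,
        imputed=np.zeros(values.size, dtype=bool),
    )


def _first_sunday_1am_hour(start_day: int) -> int:
    """Hour-of-recording index of the first Sunday 01:00 in the week."""
    return ((6 - start_day) % 7) * 24 + 1


def inject_missingness(series: EpochSeries, scenario: str,
                       rng: np.random.Generator | None = None) -> EpochSeries:
    """Degrade a complete week into one of the completeness scenarios.

    ``trailing_blank`` blanks the final epoch; ``spring_dst`` blanks the
    Sunday 01:00 hour and appends one extra trailing hour (121,680 slots at
    5 s); ``autumn_dst`` drops the final hour (120,240 slots); ``imputed_blocks``
    flags a few whole hours as upstream-imputed and overwrites them with the
    same-clock-hour mean of the other days; ``random_gaps`` scatters blank
    hours, which makes the week unusable.
    """
    eph = series.epochs_per_hour
    full = HOURS_PER_WEEK * eph
    if series.n_slots != full:
        raise ValueError("missingness scenarios start from a complete week")
    if scenario == "none":
        return series
    out = series.copy()
    if scenario == "trailing_blank":
        out.values[-1] = np.nan
        return out
    if scenario == "spring_dst":
        extra = out.values[(HOURS_PER_WEEK - 24) * eph:
                           (HOURS_PER_WEEK - 23) * eph].copy()
        h = _first_sunday_1am_hour(series.start_day)
        values = np.concatenate([out.values, extra])
        imputed = np.concatenate([out.imputed, np.zeros(eph, dtype=bool)])
        values[h * eph:(h + 1) * eph] = np.nan
        return EpochSeries(out.participant_id, out.start_timestamp,
                           out.epoch_seconds, values, imputed,
                           source_notes="spring DST transition week")
    if scenario == "autumn_dst":
        values = out.values[:-eph]
        imputed = out.imputed[:-eph]
        return EpochSeries(out.participant_id, out.start_timestamp,
                           out.epoch_seconds, values, imputed,
                           source_notes="autumn DST transition week "
                                        "(duplicated clock hour collapsed)")
    if rng is None:
        rng = np.random.default_rng(0)
    if scenario == "imputed_blocks":
        n_hours = int(rng.integers(1, 5))
        hours = rng.choice(HOURS_PER_WEEK, size=n_hours, replace=False)
        grid = out.values.reshape(HOURS_PER_WEEK, eph)
        for h in sorted(int(h) for h in hours):
            clock = h % 24
            others = [d * 24 + clock for d in range(7) if d * 24 + clock != h]
            grid[h] = grid[others].mean(axis=0)
            out.imputed[h * eph:(h + 1) * eph] = True
        return out
    if scenario == "random_gaps":
        n_hours = int(rng.integers(3, 8))
        hours = rng.choice(HOURS_PER_WEEK - 1, size=n_hours, replace=False)
        for h in hours:
            out.values[h * eph:(h + 1) * eph] = np.nan
        return out
    raise ValueError(f"unknown missingness scenario {scenario!r}")


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _plan_cohort(config: CohortConfig) -> pd.DataFrame:
    """Deterministic participant plan (truth table) for a configuration."""
    ss = np.random.SeedSequence(config.seed)
    names = list(config.archetypes)
    n_total = config.n_per_archetype * len(names) \
        + config.n_outliers_high_mean + config.n_low_wear
    children = ss.spawn(n_total + 1)
    plan_rng = np.random.default_rng(children[0])
    rows = []
    i = 0

    def _next_seed() -> int:
        nonlocal i
        i += 1
        return int(children[i].generate_state(1)[0] % (2 ** 31))

    scenarios = list(config.missingness_mix)
    probs = np.array([config.missingness_mix[s] for s in scenarios])
    probs = probs / probs.sum()
    for name in names:
        for j in range(config.n_per_archetype):
            rows.append({
                "participant_id": f"{name}_{j:04d}",
                "archetype": name,
                "scenario": str(plan_rng.choice(scenarios, p=probs)),
                "start_day": int(plan_rng.choice(7, p=config.start_day_distribution)),
                "seed": _next_seed(),
            })
    for j in range(config.n_outliers_high_mean):
        rows.append({
            "participant_id": f"outlier_high_mean_{j:04d}",
            "archetype": "outlier_high_mean",
            "scenario": "none",
            "start_day": int(plan_rng.choice(7, p=config.start_day_distribution)),
            "seed": _next_seed(),
        })
    for j in range(config.n_low_wear):
        rows.append({
            "participant_id": f"low_wear_{j:04d}",
            "archetype": str(plan_rng.choice(list(config.archetypes))),
            "scenario": "low_wear",
            "start_day": int(plan_rng.choice(7, p=config.start_day_distribution)),
            "seed": _next_seed(),
        })
    return pd.DataFrame(rows)


def _realise(row: pd.Series, config: CohortConfig,
             templates: dict[str, np.ndarray]) -> EpochSeries:
    rng = np.random.default_rng(row["seed"] + 1)
    if row["archetype"] == "outlier_high_mean":
        template = np.full(HOURS_PER_WEEK, config.outlier_level_mg)
    else:
        template = templates[row["archetype"]]
    series = simulate_participant(
        template, config, int(row["seed"]), int(row["start_day"]),
        participant_id=row["participant_id"])
    if row["scenario"] == "low_wear":
        # flag enough leading hours as imputed to fall under 72 h of
        # measured wear (168 - flagged < 72)
        eph = series.epochs_per_hour
        series.imputed[: config.low_wear_hours_flagged * eph] = True
        return series
    return inject_missingness(series, row["scenario"], rng)


def iter_cohort(config: CohortConfig) -> Iterator[tuple[EpochSeries, pd.Series]]:
    """Yield (series, truth row) one participant at a time (flat memory)."""
    plan = _plan_cohort(config)
    templates = {name: make_archetype_template(spec)
                 for name, spec in config.archetypes.items()}
    for _, row in plan.iterrows():
        yield _realise(row, config, templates), row


def simulate_cohort(config: CohortConfig) -> tuple[list[EpochSeries], pd.DataFrame]:
    """Materialise a full cohort and its truth table.

    For full-resolution cohorts (5 s epochs, hundreds of participants)
    prefer :func:`iter_cohort`, which streams instead of holding every
    epoch series in memory.
    """
    plan = _plan_cohort(config)
    templates = {name: make_archetype_template(spec)
                 for name, spec in config.archetypes.items()}
    series = [_realise(row, config, templates) for _, row in plan.iterrows()]
    return series, plan
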