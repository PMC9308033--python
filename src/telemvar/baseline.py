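"""Static and dynamic baselines, cumulative error, and mean-day error.

The central statistic scores each measurement by its distance beyond one
standard deviation from a comparative mean,

    error = max(0, |measurement − mean| / SD − 1),

so a value within 1 SD of the comparative mean scores 0 and a value 3 SD
away scores 2.  Three comparative baselines are supported:

* **static** — a single mean/SD pooled over all animals (both sexes) and
  all timepoints;
* **dynamic** — a per-minute mean/SD series pooled over animals, which
  discounts any variance that is structured in time and shared across the
  cohort (the circadian waveform, and the estrous waveform once females are
  aligned);
* **own mean day** — each animal's per-minute-of-day mean/SD across its own
  days, which measures structure *within* an individual's day.

Cumulative error is the running sum of the per-minute error magnitudes, in
units of the comparative SD.  Comparing the terminal cumulative error under
different baselines quantifies how much of the variance was structured, and
dividing by an individual's own SD separates proportional structure from
overall variability scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import CohortMatrix
from .simulate import MINUTES_PER_DAY, PhysioSeries

__all__ = [
    "SD_EPSILON",
    "StaticBaseline",
    "DynamicBaseline",
    "ErrorCurve",
    "DayProfile",
    "static_baseline",
    "dynamic_baseline",
    "error_value",
    "error_curve",
    "mean_day_profile",
    "within_day_error",
    "normalize_by_individual_sd",
    "error_reduction_percent",
]

logger = logging.getLogger(__name__)

#: Floor applied to degenerate (zero) SDs, in signal units.
SD_EPSILON = 1e-9


def _floor_sd(sd: np.ndarray | float, context: str, level: int = logging.WARNING):
    flagged = bool(np.any(np.asarray(sd) < SD_EPSILON))
    if flagged:
        logger.log(level, "%s: SD below epsilon; floored at %g", context, SD_EPSILON)
    return np.maximum(sd, SD_EPSILON), flagged


@dataclass(frozen=True)
class StaticBaseline:
    """One pooled comparative mean/SD pair."""

    mean: float
    sd: float
    flagged: bool = False


@dataclass(frozen=True)
class DynamicBaseline:
    """Per-minute comparative mean/SD series (pooled across animals)."""

    means: np.ndarray
    sds: np.ndarray
    flagged: bool = False

    def __len__(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class DayProfile:
    """An individual's mean daily profile: per-minute-of-day mean and SD."""

    animal_id: str
    minute_of_day_means: np.ndarray
    minute_of_day_sds: np.ndarray

    def __post_init__(self) -> None:
        if len(self.minute_of_day_means) != len(self.minute_of_day_sds):
            raise ValueError("profile means and sds must have equal length")

    @property
    def mean_sd(self) -> float:
        """The individual's mean SD: average of the per-minute profile SDs."""
        return float(np.mean(self.minute_of_day_sds))


@dataclass
class ErrorCurve:
    """Per-minute error values and their running cumulative sum."""

    animal_id: str
    per_minute_error: np.ndarray
    cumulative: np.ndarray
    baseline_kind: str  # static | dynamic | own_mean_day
    day_subtotals: np.ndarray | None = None

    @property
    def final(self) -> float:
        """Terminal cumulative error, in comparative-SD units."""
        return float(self.cumulative[-1])


def static_baseline(matrix: CohortMatrix) -> StaticBaseline:
    """Pooled mean/SD over all animals and all timepoints (n−1 SD)."""
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    mean = float(np.mean(matrix.values))
    sd = float(np.std(matrix.values, ddof=1)) if matrix.values.size > 1 else 0.0
    sd, flagged = _floor_sd(sd, "static baseline")
    return StaticBaseline(mean=mean, sd=float(sd), flagged=flagged)


def dynamic_baseline(matrix: CohortMatrix) -> DynamicBaseline:
    """Column-wise (per-minute) mean/SD across animals (n−1 SD)."""
    if matrix.n_animals < 2:
        raise ValueError("dynamic baseline requires at least 2 animals")
    means = np.mean(matrix.values, axis=0)
    sds = np.std(matrix.values, axis=0, ddof=1)
    sds, flagged = _floor_sd(sds, "dynamic baseline")
    return DynamicBaseline(means=means, sds=sds, flagged=flagged)


def error_value(measurement, mean, sd):
    """Distance beyond one comparative SD: ``max(0, |x − mean|/sd − 1)``.

    Vectorized over any broadcastable combination of arguments.
    """
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be > 0")
    out = np.maximum(np.abs(np.asarray(measurement, dtype=float) - mean) / sd - 1.0, 0.0)
    return float(out) if out.ndim == 0 else out


def _excess_distance(values, means, sds) -> np.ndarray:
    """Signal-unit distance beyond one comparative SD: max(0, |x−mean|−sd)."""
    return np.maximum(np.abs(values - means) - sds, 0.0)


def error_curve(
    series: PhysioSeries,
    baseline: StaticBaseline | DynamicBaseline,
    unit_sd: float | None = None,
) -> ErrorCurve:
    """Score every minute against a baseline and accumulate.

    Each minute's error is the distance beyond one comparative SD from the
    comparative mean, expressed in units of ``unit_sd``.  With ``unit_sd``
    unset, each minute is divided by its own comparative SD — exactly
    :func:`error_value`.  To compare cumulative curves *across* baselines
    (static vs. dynamic), pass a common reference — conventionally the
    static SD of the population — so all curves share one unit, the
    convention of the cumulative-error figures.
    """
    values = np.asarray(series.values, dtype=float)
    if isinstance(baseline, StaticBaseline):
        excess = _excess_distance(values, baseline.mean, baseline.sd)
        unit = baseline.sd if unit_sd is None else unit_sd
        err = excess / unit
        kind = "static"
    else:
        if len(baseline) != len(values):
            raise ValueError(
                f"dynamic baseline length {len(baseline)} != series length {len(values)}"
            )
        excess = _excess_distance(values, baseline.means, baseline.sds)
        err = excess / (baseline.sds if unit_sd is None else unit_sd)
        kind = "dynamic"
    if unit_sd is not None and unit_sd <= 0:
        raise ValueError("unit_sd must be > 0")
    return ErrorCurve(
        animal_id=series.animal_id,
        per_minute_error=err,
        cumulative=np.cumsum(err),
        baseline_kind=kind,
    )


def mean_day_profile(series: PhysioSeries) -> DayProfile:
    """Fold a whole-day record into per-minute-of-day mean and SD (n−1)."""
    spd = series.samples_per_day
    values = np.asarray(series.values, dtype=float)
    if len(values) % spd != 0:
        raise ValueError("record must contain a whole number of days")
    days = values.reshape(-1, spd)
    if days.shape[0] < 2:
        raise ValueError("mean day profile requires at least 2 days")
    return DayProfile(
        animal_id=series.animal_id,
        minute_of_day_means=days.mean(axis=0),
        minute_of_day_sds=days.std(axis=0, ddof=1),
    )


def within_day_error(
    series: PhysioSeries, profile: DayProfile, unit_sd: float | None = None
) -> ErrorCurve:
    """Score each minute against the animal's own mean day.

    Each sample is compared to its minute-of-day mean/SD — the distance
    beyond one profile SD, divided by that minute's profile SD when
    ``unit_sd`` is unset (exactly :func:`error_value`), or by ``unit_sd``
    when a common unit is wanted (``unit_sd=1.0`` keeps signal units, the
    convention for summing error across 24 h and then normalizing by the
    individual's mean SD).  The cumulative sum runs across the full record
    and per-day subtotals are retained.
    """
    if profile.animal_id != series.animal_id:
        raise ValueError(
            f"profile for {profile.animal_id} does not match series "
            f"{series.animal_id}"
        )
    spd = series.samples_per_day
    values = np.asarray(series.values, dtype=float)
    if len(values) % spd != 0:
        raise ValueError("record must contain a whole number of days")
    # zero profile SDs are routine for activity (all-zero minutes); debug only
    sds, _ = _floor_sd(
        profile.minute_of_day_sds, f"profile {profile.animal_id}", logging.DEBUG
    )
    n_days = len(values) // spd
    excess = _excess_distance(
        values.reshape(n_days, spd), profile.minute_of_day_means, sds
    )
    err = excess / (sds if unit_sd is None else unit_sd)
    flat = err.ravel()
    return ErrorCurve(
        animal_id=series.animal_id,
        per_minute_error=flat,
        cumulative=np.cumsum(flat),
        baseline_kind="own_mean_day",
        day_subtotals=err.sum(axis=1),
    )


def normalize_by_individual_sd(value, series: PhysioSeries):
    """Divide an error total by the SD of the individual's full record."""
    sd = series.sd()
    if sd <= 0:
        raise ValueError(f"series {series.animal_id} has non-positive SD")
    return value / sd


def error_reduction_percent(final_a: float, final_b: float) -> float:
    """Percent of the reference error eliminated by the comparison condition.

    ``final_a`` is the reference condition (static baseline, or staggered
    arrangement); ``final_b`` the comparison (dynamic baseline, or
    estrous-aligned).
    """
    if final_a <= 0:
        raise ValueError("reference cumulative error must be > 0")
    return 100.0 * (final_a - final_b) / final_a
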