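"""Cleaning rules and estrous alignment / maximal-staggering rearrangements.

Temperature records are floored at 35 °C (sensor dropouts read low) and then
winsorized at ±3 SD of the individual's floored record; activity records are
winsorized in the positive direction only, so genuine zero counts are never
inflated.  Female records can be circularly shifted by whole days so that
day 1 (0-based) of every female is a day of estrus ("aligned"), and any
cohort matrix can be staggered — each successive animal within a sex delayed
one day relative to the previous — to maximize estrous phase entropy across
females ("staggered"); males receive the same shifts as a manipulation
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .simulate import MINUTES_PER_DAY, PhysioSeries

__all__ = [
    "CohortMatrix",
    "clean_temperature",
    "clean_activity",
    "clean",
    "align_to_estrous",
    "stagger_individuals",
]

logger = logging.getLogger(__name__)

TEMPERATURE_FLOOR = 35.0
CLIP_SD = 3.0

ARRANGEMENTS = ("raw", "estrous_aligned", "staggered")


@dataclass(frozen=True)
class CohortMatrix:
    """Animals × minutes stack of one signal for one arrangement."""

    animal_ids: tuple[str, ...]
    sexes: tuple[str, ...]
    values: np.ndarray  # (n_animals, n_minutes)
    arrangement: str
    signal_kind: str
    estrous_day_offsets: tuple[int | None, ...] = ()

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be an animals x minutes matrix")
        if len(self.animal_ids) != self.values.shape[0]:
            raise ValueError("animal_ids length must match row count")
        if len(self.sexes) != self.values.shape[0]:
            raise ValueError("sexes length must match row count")
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"arrangement must be one of {ARRANGEMENTS}")

    @classmethod
    def from_series(
        cls, cohort: list[PhysioSeries], arrangement: str = "raw"
    ) -> "CohortMatrix":
        lengths = {len(s) for s in cohort}
        if len(lengths) != 1:
            raise ValueError("all series must have equal length")
        kinds = {s.signal_kind for s in cohort}
        if len(kinds) != 1:
            raise ValueError("all series must share one signal kind")
        return cls(
            animal_ids=tuple(s.animal_id for s in cohort),
            sexes=tuple(s.sex for s in cohort),
            values=np.vstack([np.asarray(s.values, dtype=float) for s in cohort]),
            arrangement=arrangement,
            signal_kind=kinds.pop(),
            estrous_day_offsets=tuple(s.estrous_day_offset for s in cohort),
        )

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_minutes(self) -> int:
        return self.values.shape[1]

    def row_series(self, i: int, sample_interval_min: float = 1.0) -> PhysioSeries:
        """View row ``i`` as a :class:`PhysioSeries`."""
        offset = self.estrous_day_offsets[i] if self.estrous_day_offsets else None
        return PhysioSeries(
            animal_id=self.animal_ids[i],
            sex=self.sexes[i],
            signal_kind=self.signal_kind,
            values=self.values[i],
            sample_interval_min=sample_interval_min,
            estrous_day_offset=offset,
        )


def _winsorize(values: np.ndarray, positive_only: bool, animal_id: str) -> np.ndarray:
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    if s == 0.0:
        logger.warning(
            "series %s has zero SD; +/-%g SD clipping is a no-op", animal_id, CLIP_SD
        )
        return values
    upper = m + CLIP_SD * s
    out = np.minimum(values, upper)
    if not positive_only:
        out = np.maximum(out, m - CLIP_SD * s)
    return out


def clean_temperature(series: PhysioSeries) -> PhysioSeries:
    """Floor at 35 °C, then winsorize at the individual's mean ± 3 SD.

    The clipping statistics are computed on the floored record of that
    individual.  Idempotent.
    """
    if series.signal_kind != "temperature":
        raise ValueError("clean_temperature requires a temperature series")
    if len(series) == 0:
        raise ValueError("empty series")
    floored = np.maximum(np.asarray(series.values, dtype=float), TEMPERATURE_FLOOR)
    return series.replace_values(
        _winsorize(floored, positive_only=False, animal_id=series.animal_id)
    )


def clean_activity(series: PhysioSeries) -> PhysioSeries:
    """Winsorize activity above the individual's mean + 3 SD only.

    No lower clipping and no floor: zero counts pass through untouched.
    """
    if series.signal_kind != "activity":
        raise ValueError("clean_activity requires an activity series")
    if len(series) == 0:
        raise ValueError("empty series")
    values = np.asarray(series.values, dtype=float)
    return series.replace_values(
        _winsorize(values, positive_only=True, animal_id=series.animal_id)
    )


def clean(series: PhysioSeries) -> PhysioSeries:
    """Dispatch to the signal-appropriate cleaning rule."""
    if series.signal_kind == "temperature":
        return clean_temperature(series)
    return clean_activity(series)


def _roll_days(values: np.ndarray, n_days_shift: int, samples_per_day: int) -> np.ndarray:
    return np.roll(values, n_days_shift * samples_per_day)


def align_to_estrous(cohort: list[PhysioSeries]) -> CohortMatrix:
    """Shift each female by whole days so day index 1 is a day of estrus.

    A female with ``estrous_day_offset == 1`` is already aligned and gets a
    zero shift; males are passed through untouched.  Shifts are circular
    within the record, so row lengths and value multisets are preserved.
    """
    shifted: list[PhysioSeries] = []
    for s in cohort:
        if s.sex == "female":
            if s.estrous_day_offset is None:
                raise ValueError(
                    f"female {s.animal_id} is missing estrous_day_offset"
                )
            shift = -(s.estrous_day_offset - 1)
            new = replace(
                s,
                values=_roll_days(np.asarray(s.values), shift, s.samples_per_day),
                estrous_day_offset=1,
            )
            shifted.append(new)
        else:
            shifted.append(s)
    return CohortMatrix.from_series(shifted, arrangement="estrous_aligned")


def stagger_individuals(matrix: CohortMatrix, per_sex: bool = True) -> CohortMatrix:
    """Delay each successive row by one day relative to the previous row.

    Row k (counted within its sex group when ``per_sex`` is true, matching
    the manipulation in which each individual is delayed relative to the
    previous individual *of its group*) is circularly shifted forward by
    k × 1440 minutes.  With a 4-day estrous cycle this partitions aligned
    females into 4 phase classes (k mod 4).
    """
    spd = MINUTES_PER_DAY  # 1-min sampling assumed for whole-day shifts
    if matrix.n_minutes % spd != 0:
        raise ValueError("row length must be a whole number of days (1440 min)")
    counters: dict[str, int] = {}
    rows = np.empty_like(matrix.values)
    for i in range(matrix.n_animals):
        key = matrix.sexes[i] if per_sex else "all"
        k = counters.get(key, 0)
        counters[key] = k + 1
        rows[i] = _roll_days(matrix.values[i], k, spd)
    return CohortMatrix(
        animal_ids=matrix.animal_ids,
        sexes=matrix.sexes,
        values=rows,
        arrangement="staggered",
        signal_kind=matrix.signal_kind,
        estrous_day_offsets=matrix.estrous_day_offsets,
    )
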