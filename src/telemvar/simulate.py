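"""Synthetic male/female telemetry cohorts with known ground truth.

Generates minute-resolution core body temperature (CBT, °C) and locomotor
activity (LA, counts/min) records for a cohort of mice, with controllable
structured variance — a shared ~24 h circadian rhythm, circadian-modulated
ultradian rhythms (1–3 h) whose phase drifts from day to day, and a 4-day
estrous modulation in females — plus sex-specific unstructured Gaussian
noise.  Every downstream analysis stage (baselines, wavelet band power,
day-to-day warping distance) can therefore be validated against a known
decomposition of the variance.

The generative model for one animal is

    s(t) = L + A_c·cos(2π(t − φ_c)/P_c)
             + A_u(t)·cos(θ_u(t))
             + A_e·cos(2π(t − φ_e)/P_e)
             + ε(t)

with  A_u(t) = a_u·(1 + d·cos(2π t / P_c)),  θ_u a phase accumulator that
advances by 2π·Δt/P_u per step plus Gaussian jitter (a random walk that
breaks day-to-day ultradian alignment), and ε ~ N(0, σ²) i.i.d.  For
activity the continuous signal is used as the rate of a per-minute Poisson
draw (floored at 0), so counts are nonnegative integers and zeros stay
zeros.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnimalSpec",
    "CohortConfig",
    "PhysioSeries",
    "simulate_animal",
    "simulate_cohort",
    "default_sex_profiles",
    "MINUTES_PER_DAY",
]

MINUTES_PER_DAY = 1440

SEXES = ("male", "female")
SIGNAL_KINDS = ("temperature", "activity")


@dataclass(frozen=True)
class AnimalSpec:
    """Generative parameters for one animal.

    All amplitudes are in signal units (°C for temperature, counts/min for
    activity); periods are in minutes; ``ult_mod_depth`` is the dimensionless
    depth (0–1) of circadian modulation of the ultradian amplitude;
    ``ult_phase_jitter_sd`` is the per-step SD (radians) of the ultradian
    phase random walk.
    """

    sex: str
    baseline_level: float
    circ_amp: float
    ult_amp: float
    ult_mod_depth: float
    ult_phase_jitter_sd: float
    noise_sd: float
    circ_period_min: float = 1440.0
    ult_period_min: float = 120.0
    estrous_amp: float = 0.0
    estrous_period_min: float = 5760.0
    estrous_day_offset: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name in ("circ_amp", "ult_amp", "estrous_amp", "noise_sd",
                     "ult_phase_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("circ_period_min", "ult_period_min", "estrous_period_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.ult_mod_depth <= 1.0:
            raise ValueError("ult_mod_depth must be in [0, 1]")
        if self.sex == "male" and self.estrous_amp != 0.0:
            raise ValueError("estrous_amp must be 0 for males")
        if self.estrous_day_offset is not None and not (
            0 <= self.estrous_day_offset <= 3
        ):
            raise ValueError("estrous_day_offset must be an integer in 0..3")


@dataclass(frozen=True)
class CohortConfig:
    """A cohort of ``n_males + n_females`` animals for one signal kind.

    Per-animal random streams are derived deterministically from
    ``master_seed`` and the animal index, so regenerating any one animal
    does not depend on cohort order.
    """

    n_males: int
    n_females: int
    signal_kind: str
    master_seed: int
    n_days: int = 14
    sample_interval_min: float = 1.0
    male_spec: AnimalSpec | None = None
    female_spec: AnimalSpec | None = None

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("animal counts must be >= 0")
        if self.n_males + self.n_females == 0:
            raise ValueError("cohort must contain at least one animal")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        n = self.n_days * MINUTES_PER_DAY / self.sample_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "n_days * 1440 / sample_interval_min must be an integer "
                "sample count"
            )

    @property
    def n_samples(self) -> int:
        return round(self.n_days * MINUTES_PER_DAY / self.sample_interval_min)


@dataclass
class PhysioSeries:
    """One animal's minute-resolution signal with metadata."""

    animal_id: str
    sex: str
    signal_kind: str
    values: np.ndarray
    t0_min: float = 0.0
    sample_interval_min: float = 1.0
    estrous_day_offset: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def samples_per_day(self) -> int:
        return round(MINUTES_PER_DAY / self.sample_interval_min)

    @property
    def n_days(self) -> float:
        return len(self.values) / self.samples_per_day

    def day(self, index: int) -> np.ndarray:
        """Samples of day ``index`` (0-based, half-open day windows)."""
        spd = self.samples_per_day
        if not 0 <= index < len(self.values) // spd:
            raise IndexError(f"day index {index} out of range")
        return self.values[index * spd: (index + 1) * spd]

    def sd(self, ddof: int = 1) -> float:
        """SD of the full record — the individual's own variability scale."""
        return float(np.std(self.values, ddof=ddof))

    def replace_values(self, values: np.ndarray) -> "PhysioSeries":
        return dataclasses.replace(self, values=np.asarray(values))


def _animal_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(index,))
    )


def simulate_animal(
    spec: AnimalSpec,
    n_days: int,
    interval_min: float = 1.0,
    seed: int | np.random.Generator = 0,
    animal_id: str = "A00",
    signal_kind: str = "temperature",
) -> PhysioSeries:
    """Simulate one animal's record under the additive rhythm model.

    Deterministic given ``seed``.  The deterministic components (baseline,
    circadian, estrous, and the un-jittered ultradian carrier phase) do not
    depend on the seed; only the phase jitter, the Gaussian noise and the
    Poisson link (activity) consume random numbers.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if signal_kind not in SIGNAL_KINDS:
        raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = round(n_days * MINUTES_PER_DAY / interval_min)
    t = np.arange(n) * interval_min

    signal = np.full(n, spec.baseline_level, dtype=float)
    signal += spec.circ_amp * np.cos(2 * np.pi * t / spec.circ_period_min)

    # Ultradian component: circadian-modulated amplitude, random-walk phase.
    # The starting phase is a stable per-animal constant (hashed from the
    # animal id): ultradian oscillators are not synchronized across animals,
    # and keeping it seed-independent leaves the noise-free signal identical
    # across master seeds.
    envelope = spec.ult_amp * (
        1.0 + spec.ult_mod_depth * np.cos(2 * np.pi * t / spec.circ_period_min)
    )
    theta0 = 2 * np.pi * (zlib.crc32(animal_id.encode()) % 2**16) / 2**16
    dtheta = 2 * np.pi * interval_min / spec.ult_period_min
    if spec.ult_phase_jitter_sd > 0:
        jitter = rng.normal(0.0, spec.ult_phase_jitter_sd, size=n)
    else:
        jitter = np.zeros(n)
    theta = theta0 + dtheta * np.arange(n) + np.cumsum(jitter) - jitter[0]
    signal += envelope * np.cos(theta)

    if spec.estrous_amp > 0:
        offset = spec.estrous_day_offset or 0
        # peak of the estrous modulation at the middle of the estrous day
        phi_e = (offset + 0.5) * MINUTES_PER_DAY
        signal += spec.estrous_amp * np.cos(
            2 * np.pi * (t - phi_e) / spec.estrous_period_min
        )

    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=n)

    if signal_kind == "activity":
        values: np.ndarray = rng.poisson(np.maximum(signal, 0.0)).astype(np.int64)
    else:
        values = signal

    return PhysioSeries(
        animal_id=animal_id,
        sex=spec.sex,
        signal_kind=signal_kind,
        values=values,
        sample_interval_min=interval_min,
        estrous_day_offset=spec.estrous_day_offset,
    )


def simulate_cohort(config: CohortConfig) -> list[PhysioSeries]:
    """Simulate all animals of a cohort; males first, then females.

    Female ``estrous_day_offset`` values are assigned round-robin 0,1,2,3
    unless the female template spec pins one explicitly.
    """
    male_spec, female_spec = (
        (config.male_spec, config.female_spec)
        if config.male_spec is not None and config.female_spec is not None
        else default_sex_profiles(config.signal_kind)
    )
    if config.male_spec is not None:
        male_spec = config.male_spec
    if config.female_spec is not None:
        female_spec = config.female_spec

    series: list[PhysioSeries] = []
    for i in range(config.n_males):
        series.append(
            simulate_animal(
                male_spec,
                config.n_days,
                config.sample_interval_min,
                seed=_animal_rng(config.master_seed, i),
                animal_id=f"M{i + 1:02d}",
                signal_kind=config.signal_kind,
            )
        )
    for j in range(config.n_females):
        spec = female_spec
        if spec.estrous_day_offset is None:
            spec = dataclasses.replace(spec, estrous_day_offset=j % 4)
        series.append(
            simulate_animal(
                spec,
                config.n_days,
                config.sample_interval_min,
                seed=_animal_rng(config.master_seed, config.n_males + j),
                animal_id=f"F{j + 1:02d}",
                signal_kind=config.signal_kind,
            )
        )
    return series


# Default sex profiles, version-pinned.  Magnitudes are realistic for
# C57BL/6-scale telemetry (CBT mean ≈ 36.9 °C with ≈1 °C peak-to-trough
# circadian range; activity a low-count Poisson-like process) and encode the
# orderings the analyses are designed to detect: males carry larger
# unstructured noise, larger ultradian amplitude, deeper circadian modulation
# of that amplitude and faster day-to-day ultradian phase drift; females
# alone carry a 4-day estrous modulation.
_DEFAULT_PROFILES: dict[str, tuple[AnimalSpec, AnimalSpec]] = {
    "temperature": (
        AnimalSpec(
            sex="male", baseline_level=36.9, circ_amp=0.8,
            ult_amp=0.40, ult_mod_depth=0.8, ult_phase_jitter_sd=0.06,
            noise_sd=0.35,
        ),
        AnimalSpec(
            sex="female", baseline_level=36.9, circ_amp=0.8,
            ult_amp=0.25, ult_mod_depth=0.4, ult_phase_jitter_sd=0.06,
            noise_sd=0.15, estrous_amp=0.05,
        ),
    ),
    "activity": (
        AnimalSpec(
            sex="male", baseline_level=12.0, circ_amp=10.0,
            ult_amp=6.0, ult_mod_depth=0.8, ult_phase_jitter_sd=0.06,
            noise_sd=6.0,
        ),
        AnimalSpec(
            sex="female", baseline_level=12.0, circ_amp=10.0,
            ult_amp=4.5, ult_mod_depth=0.4, ult_phase_jitter_sd=0.06,
            noise_sd=2.0, estrous_amp=1.0,
        ),
    ),
}


def default_sex_profiles(signal_kind: str) -> tuple[AnimalSpec, AnimalSpec]:
    """Return the default ``(male_spec, female_spec)`` pair for a signal."""
    try:
        return _DEFAULT_PROFILES[signal_kind]
    except KeyError:
        raise ValueError(
            f"unknown signal_kind {signal_kind!r}; expected one of {SIGNAL_KINDS}"
        ) from None
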