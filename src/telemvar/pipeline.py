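"""End-to-end orchestration: simulate → clean → arrange → analyze → report.

A :class:`RunConfig` describes one reproducible experiment: cohort sizes and
sex profiles, which arrangements (estrous-aligned / staggered) and baselines
(static / dynamic) to evaluate, and which analysis stages to run.  The
returned result bundle (and, when an output directory is given, the CSV/JSON
files) contains per-animal summaries for every stage plus the sex-contrast
report, and a manifest with the seeds and config hash needed to reproduce
every number exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baseline import (
    dynamic_baseline,
    error_curve,
    error_reduction_percent,
    mean_day_profile,
    normalize_by_individual_sd,
    static_baseline,
    within_day_error,
)
from .dtw import consecutive_day_distances, sd_normalized_distances
from .io import read_cohort_csv, write_cohort_csv
from .preprocessing import CohortMatrix, align_to_estrous, clean, stagger_individuals
from .simulate import AnimalSpec, CohortConfig, PhysioSeries, simulate_cohort
from .spectra import (
    CIRCADIAN_BAND,
    ULTRADIAN_BAND,
    band_max_power,
    band_power_summary,
    circadian_modulation_of_ultradian,
    morse_cwt,
)
from .stats import kruskal_last_hour, sex_comparison_report

__all__ = ["RunConfig", "run_pipeline", "load_external_cohort", "ConfigError"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("error", "spectra", "dtw", "stats")
SIGNALS = ("temperature", "activity")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    master_seed: int = 0
    n_males: int = 13
    n_females: int = 13
    n_days: int = 14
    arrangement: str = "both"  # estrous_aligned | staggered | both
    baselines: str = "both"  # static | dynamic | both
    stages: tuple[str, ...] = ALL_STAGES
    signals: tuple[str, ...] = SIGNALS
    spectra_signals: tuple[str, ...] = ("temperature",)
    male_specs: dict | None = None  # signal_kind -> AnimalSpec
    female_specs: dict | None = None
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.arrangement not in ("estrous_aligned", "staggered", "both"):
            raise ConfigError(f"bad arrangement {self.arrangement!r}")
        if self.baselines not in ("static", "dynamic", "both"):
            raise ConfigError(f"bad baselines {self.baselines!r}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        unknown = set(self.signals) - set(SIGNALS)
        if unknown:
            raise ConfigError(f"unknown signals {sorted(unknown)}")

    @property
    def effective_stages(self) -> tuple[str, ...]:
        """Requested stages with dependencies auto-enabled (stats → all)."""
        stages = set(self.stages)
        if "stats" in stages:
            stages |= {"error", "dtw", "spectra"}
        return tuple(s for s in ALL_STAGES if s in stages)

    @property
    def arrangements(self) -> tuple[str, ...]:
        return (
            ("estrous_aligned", "staggered")
            if self.arrangement == "both"
            else (self.arrangement,)
        )

    @property
    def baseline_kinds(self) -> tuple[str, ...]:
        return ("static", "dynamic") if self.baselines == "both" else (self.baselines,)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("male_specs", "female_specs"):
            if d[key] is not None:
                d[key] = {
                    k: dataclasses.asdict(v) if isinstance(v, AnimalSpec) else dict(v)
                    for k, v in d[key].items()
                }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("male_specs", "female_specs"):
            if d.get(key):
                d[key] = {k: AnimalSpec(**v) if not isinstance(v, AnimalSpec) else v
                          for k, v in d[key].items()}
        for key in ("stages", "signals", "spectra_signals"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _signal_seeds(master_seed: int, signals: tuple[str, ...]) -> dict[str, int]:
    state = np.random.SeedSequence(master_seed).generate_state(len(signals))
    return {sig: int(s % (2**31)) for sig, s in zip(signals, state)}


def simulate_and_clean(config: RunConfig, signal: str, seed: int) -> list[PhysioSeries]:
    cohort_cfg = CohortConfig(
        n_males=config.n_males,
        n_females=config.n_females,
        signal_kind=signal,
        master_seed=seed,
        n_days=config.n_days,
        male_spec=(config.male_specs or {}).get(signal),
        female_spec=(config.female_specs or {}).get(signal),
    )
    return [clean(s) for s in simulate_cohort(cohort_cfg)]


def _error_stage(config, cleaned, matrices, signal):
    rows = []
    finals: dict[tuple[str, str], dict[str, float]] = {}
    for arrangement in config.arrangements:
        matrix = matrices[arrangement]
        # one common unit (the static SD of the population) per arrangement,
        # so static and dynamic cumulative curves are directly comparable
        static = static_baseline(matrix)
        for kind in config.baseline_kinds:
            baseline = static if kind == "static" else dynamic_baseline(matrix)
            for i in range(matrix.n_animals):
                row = matrix.row_series(i)
                curve = error_curve(row, baseline, unit_sd=static.sd)
                final = curve.final
                rows.append(
                    {
                        "animal_id": row.animal_id,
                        "sex": row.sex,
                        "signal": signal,
                        "arrangement": arrangement,
                        "baseline_kind": kind,
                        "final_cumulative": final,
                        "sd_normalized_final": normalize_by_individual_sd(final, row),
                    }
                )
                finals.setdefault((arrangement, kind), {})[row.animal_id] = final
    # within-individual mean-day error (arrangement-independent): raw error
    # summed in signal units, then normalized by the individual's mean SD
    # (the average of its per-minute-of-day profile SDs)
    wd_rows = []
    for s in cleaned:
        profile = mean_day_profile(s)
        curve = within_day_error(s, profile, unit_sd=1.0)
        wd_rows.append(
            {
                "animal_id": s.animal_id,
                "sex": s.sex,
                "signal": signal,
                "final_cumulative": curve.final,
                "sd_normalized_final": curve.final / max(profile.mean_sd, 1e-9),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(wd_rows), finals


def _curves_last_hour(config, matrices, signal):
    """Error curves by sex for the Kruskal-Wallis last-hour tests."""
    out = {}
    arrangement = (
        "staggered" if "staggered" in config.arrangements else config.arrangements[0]
    )
    matrix = matrices[arrangement]
    static = static_baseline(matrix)
    for kind in config.baseline_kinds:
        baseline = static if kind == "static" else dynamic_baseline(matrix)
        by_sex = {"male": [], "female": []}
        for i in range(matrix.n_animals):
            row = matrix.row_series(i)
            by_sex[row.sex].append(error_curve(row, baseline, unit_sd=static.sd))
        out[kind] = {k: v for k, v in by_sex.items() if v}
    return out, arrangement


def _spectra_stage(config, cleaned, signal):
    rows = []
    for s in cleaned:
        wpm = morse_cwt(s)
        ult = band_max_power(wpm, *ULTRADIAN_BAND)
        first = band_power_summary(ult)
        second = band_power_summary(circadian_modulation_of_ultradian(s))
        for order, band, summ in (
            ("first", ULTRADIAN_BAND, first),
            ("second", CIRCADIAN_BAND, second),
        ):
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "sex": s.sex,
                    "signal": signal,
                    "band": f"{band[0]:g}-{band[1]:g}",
                    "order": order,
                    "mean": summ["mean"],
                    "median": summ["median"],
                }
            )
    return pd.DataFrame(rows)


def _dtw_stage(config, matrices, signal):
    arrangement = (
        "staggered" if "staggered" in config.arrangements else config.arrangements[0]
    )
    matrix = matrices[arrangement]
    rows = []
    for i in range(matrix.n_animals):
        row = matrix.row_series(i)
        distances = consecutive_day_distances(row)
        normalized = sd_normalized_distances(distances, row)
        for k, (d, nd) in enumerate(zip(distances, normalized)):
            rows.append(
                {
                    "animal_id": row.animal_id,
                    "sex": row.sex,
                    "signal": signal,
                    "day_a": k,
                    "day_b": k + 1,
                    "distance": d,
                    "normalized_distance": nd,
                }
            )
    return pd.DataFrame(rows)


def _sex_values(df: pd.DataFrame, column: str):
    male = df.loc[df["sex"] == "male", column].to_numpy()
    female = df.loc[df["sex"] == "female", column].to_numpy()
    return male, female


def build_contrasts(results: dict) -> dict:
    """Per-animal summary values for every sex contrast in the report."""
    contrasts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for signal, err in results.get("error_summary", {}).items():
        arrangements = err["arrangement"].unique()
        # the primary sex comparison uses maximally staggered females
        arrangement = "staggered" if "staggered" in arrangements else arrangements[0]
        for kind in err["baseline_kind"].unique():
            sub = err[
                (err["baseline_kind"] == kind)
                & (err["arrangement"] == arrangement)
            ]
            contrasts[f"cumulative_error_{kind}_{signal}"] = _sex_values(
                sub, "final_cumulative"
            )
    for signal, wd in results.get("within_day", {}).items():
        contrasts[f"within_day_error_{signal}"] = _sex_values(wd, "final_cumulative")
        contrasts[f"within_day_error_sdnorm_{signal}"] = _sex_values(
            wd, "sd_normalized_final"
        )
    for signal, dtw_df in results.get("dtw", {}).items():
        per_animal = dtw_df.groupby(["animal_id", "sex"], as_index=False)[
            ["distance", "normalized_distance"]
        ].mean()
        contrasts[f"dtw_distance_{signal}"] = _sex_values(per_animal, "distance")
        contrasts[f"dtw_distance_sdnorm_{signal}"] = _sex_values(
            per_animal, "normalized_distance"
        )
    for signal, bp in results.get("band_power", {}).items():
        for order, label in (("first", "ultradian_power_median"),
                             ("second", "circadian_of_ultradian_median")):
            sub = bp[bp["order"] == order]
            contrasts[f"{label}_{signal}"] = _sex_values(sub, "median")
    return contrasts


def _reductions(finals_by_signal: dict, error_by_signal: dict) -> dict:
    """Static→dynamic and staggered→aligned error reductions, percent."""
    out: dict[str, float] = {}
    for signal, finals in finals_by_signal.items():
        def _mean(arrangement, kind, sex=None):
            key = (arrangement, kind)
            if key not in finals:
                return None
            err = error_by_signal[signal]
            sub = err[(err["arrangement"] == arrangement) & (err["baseline_kind"] == kind)]
            if sex:
                sub = sub[sub["sex"] == sex]
            return float(sub["final_cumulative"].mean()) if len(sub) else None

        for arrangement in ("staggered", "estrous_aligned"):
            a, b = _mean(arrangement, "static"), _mean(arrangement, "dynamic")
            if a and b is not None:
                out[f"{signal}.{arrangement}.static_to_dynamic_pct"] = (
                    error_reduction_percent(a, b)
                )
        for sex in ("female", "male"):
            a = _mean("staggered", "dynamic", sex)
            b = _mean("estrous_aligned", "dynamic", sex)
            if a and b is not None:
                out[f"{signal}.dynamic.staggered_to_aligned_{sex}_pct"] = (
                    error_reduction_percent(a, b)
                )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the result bundle.

    Deterministic: re-running with the same config reproduces identical
    numeric content.  When ``config.output_dir`` is set, stage summaries,
    the contrast report and a manifest are written there.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stages = config.effective_stages
    seeds = _signal_seeds(config.master_seed, tuple(config.signals))
    results: dict = {
        "error_summary": {}, "within_day": {}, "dtw": {},
        "band_power": {}, "kruskal": {}, "reductions": {},
    }
    finals_by_signal: dict[str, dict] = {}

    for signal in config.signals:
        try:
            cleaned = simulate_and_clean(config, signal, seeds[signal])
            aligned = align_to_estrous(cleaned)
            matrices = {"estrous_aligned": aligned,
                        "staggered": stagger_individuals(aligned)}
            if "error" in stages:
                err, wd, finals = _error_stage(config, cleaned, matrices, signal)
                results["error_summary"][signal] = err
                results["within_day"][signal] = wd
                finals_by_signal[signal] = finals
                curves, arrangement = _curves_last_hour(config, matrices, signal)
                for kind, by_sex in curves.items():
                    if len(by_sex) == 2:
                        key = f"{signal}.{kind}.{arrangement}"
                        results["kruskal"][key] = kruskal_last_hour(by_sex)
                        results["kruskal"][f"{key}.per_animal"] = (
                            kruskal_last_hour(by_sex, per_animal_mean=True)
                        )
            if "spectra" in stages and signal in config.spectra_signals:
                results["band_power"][signal] = _spectra_stage(config, cleaned, signal)
            if "dtw" in stages:
                results["dtw"][signal] = _dtw_stage(config, matrices, signal)
        except Exception as exc:
            raise RuntimeError(f"stage failure for signal {signal!r}: {exc}") from exc

    if "error" in stages:
        results["reductions"] = _reductions(finals_by_signal, results["error_summary"])
    if "stats" in stages:
        results["report"] = sex_comparison_report(build_contrasts(results))

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "signal_seeds": seeds,
        "stages": list(stages),
        "n_animals": config.n_males + config.n_females,
        "row_counts": {
            key: {sig: len(df) for sig, df in results[key].items()}
            for key in ("error_summary", "within_day", "dtw", "band_power")
        },
    }
    results["manifest"] = manifest

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, name in (
            ("error_summary", "error_summary.csv"),
            ("within_day", "within_day_error.csv"),
            ("dtw", "dtw_distances.csv"),
            ("band_power", "band_power_summary.csv"),
        ):
            if results[key]:
                pd.concat(results[key].values(), ignore_index=True).to_csv(
                    out / name, index=False
                )
        if results["reductions"]:
            (out / "reduction_report.json").write_text(
                json.dumps(results["reductions"], indent=2, sort_keys=True)
            )
        if "report" in results:
            results["report"].to_csv(out / "sex_contrast_report.csv", index=False)
        if results["kruskal"]:
            (out / "kruskal_last_hour.json").write_text(
                json.dumps(
                    {
                        k: {
                            "chi2": r.statistic_value,
                            "p": r.p_value,
                            "direction": r.effect_direction,
                        }
                        for k, r in results["kruskal"].items()
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def load_external_cohort(path: str | Path) -> list[PhysioSeries]:
    """Load real telemetry in the long-format schema, with validation."""
    return read_cohort_csv(path)
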