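"""Long-format cohort CSV reading/writing and matrix export.

The interchange schema is one row per sample:

    animal_id,sex,minute,value,signal_kind,estrous_day_offset

with ``minute`` 0-based from recording start.  Loading validates the schema,
requires contiguous minutes per animal (telemetry records here are gapless),
and rejects negative activity counts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import CohortMatrix
from .simulate import PhysioSeries

__all__ = ["write_cohort_csv", "read_cohort_csv", "write_matrix_csv",
           "DataValidationError"]

_COLUMNS = ["animal_id", "sex", "minute", "value", "signal_kind",
            "estrous_day_offset"]


class DataValidationError(ValueError):
    """An external cohort file violates the interchange schema."""


def write_cohort_csv(cohort: list[PhysioSeries], path: str | Path) -> None:
    frames = []
    for s in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": s.animal_id,
                    "sex": s.sex,
                    "minute": np.arange(len(s)) * s.sample_interval_min
                    + s.t0_min,
                    "value": s.values,
                    "signal_kind": s.signal_kind,
                    "estrous_day_offset": (
                        "" if s.estrous_day_offset is None else s.estrous_day_offset
                    ),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PhysioSeries]:
    """Load and validate a long-format cohort CSV."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"missing columns: {sorted(missing)}")
    cohort: list[PhysioSeries] = []
    for animal_id, g in df.groupby("animal_id", sort=False):
        g = g.sort_values("minute")
        minutes = g["minute"].to_numpy(dtype=float)
        if len(minutes) < 2:
            raise DataValidationError(f"animal {animal_id}: fewer than 2 samples")
        steps = np.diff(minutes)
        interval = steps[0]
        bad = np.nonzero(np.abs(steps - interval) > 1e-9)[0]
        if len(bad):
            raise DataValidationError(
                f"animal {animal_id}: non-contiguous minutes at minute "
                f"{minutes[bad[0]]:g}"
            )
        kinds = g["signal_kind"].unique()
        if len(kinds) != 1:
            raise DataValidationError(f"animal {animal_id}: mixed signal kinds")
        values = g["value"].to_numpy(dtype=float)
        if kinds[0] == "activity" and (values < 0).any():
            raise DataValidationError(
                f"animal {animal_id}: negative activity counts"
            )
        offsets = g["estrous_day_offset"].dropna().unique()
        offset = int(offsets[0]) if len(offsets) else None
        cohort.append(
            PhysioSeries(
                animal_id=str(animal_id),
                sex=str(g["sex"].iloc[0]),
                signal_kind=str(kinds[0]),
                values=values,
                t0_min=float(minutes[0]),
                sample_interval_min=float(interval),
                estrous_day_offset=offset,
            )
        )
    if not cohort:
        raise DataValidationError("no animals in file")
    return cohort


def write_matrix_csv(matrix: CohortMatrix, path: str | Path) -> None:
    """Wide export (rows = animals, columns = minutes) plus sidecar metadata."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=list(matrix.animal_ids))
    df.index.name = "animal_id"
    df.to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    sidecar.write_text(
        f"arrangement={matrix.arrangement}\n"
        f"signal_kind={matrix.signal_kind}\n"
        f"n_animals={matrix.n_animals}\n"
        f"n_minutes={matrix.n_minutes}\n"
    )
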