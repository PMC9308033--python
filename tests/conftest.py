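import dataclasses
import logging

import numpy as np
import pytest

import telemvar as tv

logging.disable(logging.WARNING)


@pytest.fixture
def flat_spec():
    """A degenerate animal: no rhythms, no noise — constant 37.0."""
    return tv.AnimalSpec(
        sex="male", baseline_level=37.0, circ_amp=0.0, ult_amp=0.0,
        ult_mod_depth=0.0, ult_phase_jitter_sd=0.0, noise_sd=0.0,
    )


@pytest.fixture
def quiet_male():
    """Noise-free, jitter-free male with all rhythms: every day identical."""
    return tv.AnimalSpec(
        sex="male", baseline_level=36.9, circ_amp=0.8, ult_amp=0.4,
        ult_mod_depth=0.8, ult_phase_jitter_sd=0.0, noise_sd=0.0,
    )


def make_series(values, signal_kind="temperature", animal_id="A00", sex="male",
                estrous_day_offset=None):
    return tv.PhysioSeries(
        animal_id=animal_id, sex=sex, signal_kind=signal_kind,
        values=np.asarray(values, dtype=float),
        estrous_day_offset=estrous_day_offset,
    )


@pytest.fixture
def series_factory():
    return make_series
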