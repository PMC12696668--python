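import pytest

from tusmep.synthetic import (EmgGenConfig, FieldGenConfig,
                              generate_emg_cohort, generate_pressure_field)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort with synthesized waveforms (4 participants, FDI)."""
    cfg = EmgGenConfig(n_participants=4, muscles=("FDI",), muscle_scale=(1.0,),
                       seed=3)
    return generate_emg_cohort(cfg, waveforms=True)


@pytest.fixture(scope="session")
def fast_cohort():
    """Amplitude-table cohort at study size, single muscle."""
    cfg = EmgGenConfig(muscles=("FDI",), muscle_scale=(1.0,), seed=11)
    return generate_emg_cohort(cfg, waveforms=False)


@pytest.fixture(scope="session")
def centered_field():
    """Deterministic field: no jitter, no bias, fixed 1.2 W/cm^2 peak."""
    cfg = FieldGenConfig(placement_bias=(0.0, 0.0, 0.0),
                         placement_sd=(0.0, 0.0, 0.0),
                         peak_insitu_isppa_sd=0.0, seed=1)
    pressure, head = generate_pressure_field(cfg)
    return cfg, pressure, head
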