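import numpy as np
import pytest

from lsfg.synthetic import SubjectProfile
from lsfg.waveform import PulseCycle


def make_profile(**overrides) -> SubjectProfile:
    """A mid-aged reference subject; override any field per test."""
    kw = dict(
        subject_id="S001",
        age=48.0,
        sex="female",
        heart_rate=70.0,
        mbr_baseline=7.0,
        pulse_amplitude=10.0,
        systolic_rise_fraction=0.30,
        diastolic_decay_tau=0.55,
        sbp=128.0,
        dbp=81.0,
        iop=12.8,
        measurement_noise_sd=0.0,
        between_scan_sd=0.0,
    )
    kw.update(overrides)
    return SubjectProfile(**kw)


def make_cycle(values, duration: float = 1.0) -> PulseCycle:
    return PulseCycle(phase_values=np.asarray(values, dtype=float),
                      cycle_duration=duration)


@pytest.fixture
def profile() -> SubjectProfile:
    return make_profile()


@pytest.fixture
def triangle_cycle() -> PulseCycle:
    """Symmetric triangle over 30 bins, min 0 at bin 0, max 1 at bin 15."""
    k = np.arange(30)
    v = np.where(k <= 15, k / 15.0, (30 - k) / 15.0)
    return make_cycle(v)
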