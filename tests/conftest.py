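import numpy as np
import pytest

from puwarn.series import SubjectProfile, VitalSeries
from puwarn.simulate import GeneratorConfig, PressureEventSpec, generate_subject


def make_vitals(spo2, hr=None, temp=None, valid=None, interval=1, t0=0):
    """Small helper: build a VitalSeries from plain lists; None -> blank."""
    spo2 = np.array([np.nan if v is None else v for v in spo2], dtype=float)
    n = spo2.size
    hr = np.full(n, 65.0) if hr is None else np.asarray(hr, dtype=float)
    temp = np.full(n, 35.5) if temp is None else np.asarray(temp, dtype=float)
    kwargs = {}
    if valid is not None:
        kwargs["spo2_valid"] = np.asarray(valid, dtype=bool) & ~np.isnan(spo2)
    return VitalSeries(
        t=np.arange(n, dtype=np.int64) * interval + t0,
        spo2=spo2, hr=hr, temp=temp, interval=interval, **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def patient_profile():
    return SubjectProfile(subject_id="P001", group="patient")


@pytest.fixture
def control_profile():
    return SubjectProfile(subject_id="C001", group="control")


@pytest.fixture
def quiet_config():
    """Noise-free, corruption-free generator config."""
    from puwarn.simulate import GroupParams

    params = {
        "patient": GroupParams(91.3, 0.0, 70.2, 0.0, 36.0, 0.0),
        "control": GroupParams(98.5, 0.0, 57.4, 0.0, 35.3, 0.0),
    }
    return GeneratorConfig(
        duration=600,
        group_params=params,
        pressure_noise_sd=0.0,
        temp_coupling_gain=0.0,
        seed=0,
    )


@pytest.fixture
def event_config():
    """Config with three well-separated pressure events and clean channels."""
    return GeneratorConfig(
        duration=2400,
        seed=3,
        invalid_fraction=0.0,
        pressure_noise_sd=0.01,
        pressure_events=(
            PressureEventSpec(start=300, duration=20, amplitude=5.0),
            PressureEventSpec(start=900, duration=40, amplitude=5.0),
            PressureEventSpec(start=1500, duration=60, amplitude=5.0),
        ),
    )


@pytest.fixture
def random_vitals(rng):
    """A moderately messy random series for oracle-equivalence tests."""
    n = 500
    spo2 = rng.normal(93, 4, n)
    spo2[rng.random(n) < 0.15] = np.nan
    hr = rng.normal(70, 15, n)
    hr[rng.random(n) < 0.1] = np.nan
    temp = rng.normal(36, 1, n)
    temp[rng.random(n) < 0.05] = np.nan
    return VitalSeries(t=np.arange(n, dtype=np.int64), spo2=spo2, hr=hr, temp=temp)
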