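import numpy as np
import pytest

from ecgload.synthetic import NoiseSpec, SessionSpec, generate_rr_series, synthesize_ecg


def clean_spec(**overrides) -> SessionSpec:
    """A moderate training-type session with no corruption."""
    params = dict(
        subject_id="S000",
        sex="male",
        session_type="training",
        duration_min=2.0,
        mean_hr=142.6,
        resting_hr=62.8,
        max_hr=200.9,
        lf_hf_target=1.33,
        rmssd_target=56.1,
        noise_profile=NoiseSpec(),
        seed=7,
    )
    params.update(overrides)
    return SessionSpec(**params)


@pytest.fixture
def spec() -> SessionSpec:
    return clean_spec()


@pytest.fixture
def clean_record(spec):
    return synthesize_ecg(generate_rr_series(spec), spec)


@pytest.fixture
def long_rr():
    s = clean_spec(duration_min=6.0, seed=21)
    return generate_rr_series(s)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
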