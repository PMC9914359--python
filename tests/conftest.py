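import numpy as np
import pytest

from edrcomplex import (
    RSAParams,
    RespRateProcess,
    render_ecg,
    simulate_resp_rate_trace,
    simulate_rpeak_train,
)
from edrcomplex.synthetic import CohortSpec, generate_cohort


def make_clean_ecg(
    duration=300.0,
    base_rate=0.25,
    modulation_sd=0.02,
    mean_hr=75.0,
    rsa_depth=5.0,
    jitter=0.5,
    fs=128.0,
    noise_sd=0.0,
    seed=0,
):
    """Synthetic annotated ECG with respiratory sinus arrhythmia."""
    proc = RespRateProcess(base_rate=base_rate, modulation_sd=modulation_sd, seed=seed)
    resp = simulate_resp_rate_trace(proc, duration=duration, fs_out=8.0)
    rsa = RSAParams(mean_hr=mean_hr, rsa_depth=rsa_depth, hr_jitter_sd=jitter)
    train = simulate_rpeak_train(rsa, resp, duration=duration, seed=seed + 1)
    ecg = render_ecg(train, fs=fs, noise_sd=noise_sd, seed=seed + 2)
    return ecg, train


@pytest.fixture(scope="session")
def clean_ecg():
    return make_clean_ecg()


@pytest.fixture(scope="session")
def cohort():
    """Feature-mode cohort with the default (published-table) calibration."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
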