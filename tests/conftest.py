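import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smorepars as sp
from smorepars.synthdata import SyntheticTruth, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_truth_params():
    """Control surrogate truth used across recovery-style tests."""
    return sp.SMControlParams(lam=0.08, alpha=0.06, K=2500.0)


@pytest.fixture(scope="session")
def noisy_control_dataset(control_truth_params):
    """One synthetic noisy control-arm dataset (5% CV, 3 replicates)."""
    truth = SyntheticTruth(
        generator="surrogate", sm_params=control_truth_params, doses=(0.0,), cv=0.05
    )
    return generate_dataset(truth, rng_seed=11)


@pytest.fixture(scope="session")
def control_fit(noisy_control_dataset):
    calib = sp.SurrogateCalibration(noisy_control_dataset, model="control")
    return calib.fit(n_starts=8, seed=0)


@pytest.fixture(scope="session")
def small_abm_output():
    """Small untreated ABM run shared by output-shape tests."""
    control = sp.ABMControlParams(K_A=900, s=1.0)
    return sp.simulate(control, t_grid=[0.0, 10.0, 24.0, 48.0], n_reps=4, rng_seed=5)
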