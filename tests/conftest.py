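"""Shared fixtures: calibrated walkers and the ensemble experiment cells.

Calibration and the 20-run ensembles are expensive, so they are computed
once per session and shared between the unit tests and the acceptance
tests.  Hypothesis runs derandomized so the suite is reproducible.
"""

import math

import pytest
from hypothesis import HealthCheck, settings

from stridewalk import (DiskParams, ExperimentConfig, WalkerParams,
                        calibrate_disk_noise, calibrate_k0, calibrate_sigma,
                        run_experiment)

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

PI12 = math.pi / 12
PI6 = math.pi / 6


@pytest.fixture(scope="session")
def pi12_k0():
    return calibrate_k0(WalkerParams(theta0=PI12, k0=100.0))


@pytest.fixture(scope="session")
def pi6_k0():
    return calibrate_k0(WalkerParams(theta0=PI6, k0=1000.0))


@pytest.fixture(scope="session")
def pi12_walker(pi12_k0):
    """Deterministic pi/12 walker at the calibrated speed."""
    return WalkerParams(theta0=PI12, k0=pi12_k0)


@pytest.fixture(scope="session")
def pi6_walker(pi6_k0):
    return WalkerParams(theta0=PI6, k0=pi6_k0)


@pytest.fixture(scope="session")
def pi12_noisy(pi12_walker):
    """Noisy pi/12 walker with sigma calibrated to 3% COV at 500 strides."""
    sigma = calibrate_sigma(pi12_walker)
    return pi12_walker.with_noise(sigma ** 2)


@pytest.fixture(scope="session")
def pi6_noisy(pi6_walker):
    sigma = calibrate_sigma(pi6_walker)
    return pi6_walker.with_noise(sigma ** 2)


@pytest.fixture(scope="session")
def disk_force_sd():
    return calibrate_disk_noise(DiskParams())


@pytest.fixture(scope="session")
def pi12_summary_500(pi12_noisy):
    """20 noisy pi/12 runs of 500 strides (fresh seeds 1..20)."""
    cfg = ExperimentConfig(case="walker_pi12", n_strides=500, n_runs=20,
                           base_seed=1, k0=pi12_noisy.k0,
                           sigma2=pi12_noisy.sigma2)
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def pi6_summary_500(pi6_noisy):
    cfg = ExperimentConfig(case="walker_pi6", n_strides=500, n_runs=20,
                           base_seed=1, k0=pi6_noisy.k0,
                           sigma2=pi6_noisy.sigma2)
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def pi6_summary_3000(pi6_noisy):
    """10 noisy pi/6 runs of 3,000 strides (scaled-down replication)."""
    cfg = ExperimentConfig(case="walker_pi6", n_strides=3000, n_runs=10,
                           base_seed=1, k0=pi6_noisy.k0,
                           sigma2=pi6_noisy.sigma2)
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def disk_summary_500(disk_force_sd):
    cfg = ExperimentConfig(case="rolling_disk", n_strides=500, n_runs=20,
                           base_seed=1, force_sd=disk_force_sd)
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def white_summary_500():
    cfg = ExperimentConfig(case="white_noise", n_strides=500, n_runs=20,
                           base_seed=1)
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def brownian_summary_500():
    cfg = ExperimentConfig(case="brownian", n_strides=500, n_runs=20,
                           base_seed=1)
    return run_experiment(cfg)
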