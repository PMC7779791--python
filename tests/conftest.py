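import numpy as np
import pytest

from tepnet.simulate import EpochSet, SimulationConfig, simulate_cohort


def make_epochset(data, electrodes, sampling_rate=1000.0, pre_ms=100.0,
                  subjects=None, conditions=("single", "inhibitory")):
    """Build an EpochSet from an array shaped (sub, cond, elec, epoch, time)."""
    data = np.asarray(data, dtype=float)
    n_times = data.shape[-1]
    step = 1000.0 / sampling_rate
    times = np.arange(n_times) * step - pre_ms
    if subjects is None:
        subjects = [f"S{i:03d}" for i in range(data.shape[0])]
    return EpochSet(
        data=data,
        retained=np.ones(data.shape[:4], dtype=bool),
        subjects=subjects,
        conditions=tuple(conditions)[: data.shape[1]],
        electrodes=list(electrodes),
        times=times,
        sampling_rate=sampling_rate,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_healthy=8, n_injured=6, epochs_per_condition=6,
        sampling_rate=500.0, noise_sd=1.5, artifact_rate=0.0,
        severity_mean=0.6, severity_sd=0.15, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = SimulationConfig(
        n_healthy=4, n_injured=3, epochs_per_condition=4,
        sampling_rate=500.0, noise_sd=0.0, artifact_rate=0.0,
        severity_mean=0.5, severity_sd=0.0, fa_noise_sd=0.0, seed=3)
    return simulate_cohort(cfg)
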