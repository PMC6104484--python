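import numpy as np
import pytest

from ptkit import (
    ImuRecording,
    SimulationConfig,
    PTSpec,
    default_benchmark,
    detect_full,
    simulate_session,
)

FS = 128.0
G0 = 9.81


def still_recording(duration_s: float = 10.0, fs: float = FS) -> ImuRecording:
    """Perfectly still, upright, noise-free recording."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    accel = np.tile([G0, 0.0, 0.0], (n, 1))
    gyro = np.zeros((n, 3))
    return ImuRecording(fs, t, accel, gyro)


@pytest.fixture(scope="session")
def still_rec() -> ImuRecording:
    return still_recording(20.0)


@pytest.fixture(scope="session")
def benchmark_session():
    """One default benchmark session plus its detection result (seed 1)."""
    rec, truth = default_benchmark(1)
    return rec, truth, detect_full(rec)


def single_sist_config(noise: bool = False, seed: int = 7) -> SimulationConfig:
    """One clean sit-to-stand in a 30 s session."""
    return SimulationConfig(
        seed=seed,
        duration=30.0,
        pt_schedule=[PTSpec(12.0, "SiSt")],
        gyro_bias=(0.0, 0.0, 0.0),
        noise_accel=0.05 if noise else 0.0,
        noise_gyro=0.01 if noise else 0.0,
    )


@pytest.fixture(scope="session")
def single_sist():
    return simulate_session(single_sist_config())


@pytest.fixture(scope="session")
def single_sist_noisy():
    return simulate_session(single_sist_config(noise=True))
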