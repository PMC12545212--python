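import numpy as np
import pytest

from octokin import ArmSimConfig, GaitSimConfig, simulate_arm_stride, simulate_gait


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def short_stride():
    """One cheap simulated stride (0.5 s at 60 fps) with its truth."""
    cfg = ArmSimConfig(cycle_duration=0.5, seed=7)
    traj, truth = simulate_arm_stride(cfg)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def simple_gait():
    cfg = GaitSimConfig(
        period_s=30.0,
        duty=0.6,
        phase=[0.0, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875],
        duration_s=300.0,
        fps=60.0,
        seed=11,
    )
    phase, truth = simulate_gait(cfg)
    return cfg, phase, truth
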