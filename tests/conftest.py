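import numpy as np
import pytest

from ethoquartet import AnalysisConfig
from ethoquartet.simulate import (
    SimulationConfig,
    simulate_pair_with_usv,
    simulate_quartet,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def quartet_sim():
    """A short default-condition quartet simulation."""
    return simulate_quartet(SimulationConfig(n_animals=4, duration_s=120), seed=11)


@pytest.fixture(scope="session")
def pair_sim():
    """A short same-genotype pair simulation with USVs."""
    return simulate_pair_with_usv(
        SimulationConfig(n_animals=2, duration_s=180), seed=12
    )


@pytest.fixture(scope="session")
def quartet_ethogram(quartet_sim, config):
    from ethoquartet.detection import detect_all

    traj, design, truth = quartet_sim
    return detect_all(traj, config)


def make_static_pair(n_frames=20, separation=30.0, fps=30.0):
    """Two stationary animals separated along x; no events of any type."""
    from ethoquartet.model import AnimalTrack, TrajectorySet

    def track(x):
        center = np.tile([x, 25.0], (n_frames, 1)).astype(float)
        return AnimalTrack(
            nose=center + [2.0, 0.0],
            center=center,
            tail=center - [2.0, 0.0],
            body_slope=np.full(n_frames, 0.1),
            detected=np.ones(n_frames, bool),
        )

    return TrajectorySet(
        {"a": track(10.0), "b": track(10.0 + separation)},
        fps=fps,
        arena_size_cm=(50.0, 50.0),
    )
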