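import numpy as np
import pytest

from pulsedecomp import FitConfig, GaussianTriplet, PulseGroundTruth, TrainSpec


@pytest.fixture
def example_triplet() -> GaussianTriplet:
    """A well-separated three-Gaussian pulse shape used across tests."""
    return GaussianTriplet(h=(0.8, 0.6, 0.3), w=(60.0, 90.0, 120.0), c=(150.0, 260.0, 450.0))


@pytest.fixture
def example_gt(example_triplet) -> PulseGroundTruth:
    return PulseGroundTruth(h=example_triplet.h, w=example_triplet.w, c=example_triplet.c)


@pytest.fixture
def clean_train_spec() -> TrainSpec:
    return TrainSpec(n_beats=15, fs=1000.0, mean_rr=0.9, rr_jitter_sd=0.02, seed=7)


@pytest.fixture
def fast_fit_config() -> FitConfig:
    """Reduced swarm settings for tests where fit quality is not the point."""
    return FitConfig(swarm_size=16, stage1_iters=40, stage2_iters=15, max_restarts=2, seed=0)


def random_physiological_triplet(rng: np.random.Generator) -> GaussianTriplet:
    """Draw a plausible radial-pulse shape: early forward wave, mid reflection, late tail."""
    c1 = rng.uniform(100, 180)
    c2 = c1 + rng.uniform(80, 140)
    c3 = c2 + rng.uniform(120, 250)
    return GaussianTriplet(
        h=(rng.uniform(0.5, 0.9), rng.uniform(0.4, 0.8), rng.uniform(0.2, 0.45)),
        w=(rng.uniform(40, 70), rng.uniform(70, 110), rng.uniform(100, 220)),
        c=(c1, c2, c3),
    )
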