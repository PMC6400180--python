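import numpy as np
import pytest

from spisort.preprocess import preprocess_stack
from spisort.simdata import (
    DetectorGeometry,
    ParticleModel,
    SimConfig,
    generate_dataset,
    ground_truth_intensity,
    make_icosahedron_density,
)


@pytest.fixture(scope="session")
def particle_model():
    return ParticleModel()


@pytest.fixture(scope="session")
def ground_truth_volume(particle_model):
    density = make_icosahedron_density(particle_model)
    return ground_truth_intensity(density, 3.0)


@pytest.fixture(scope="session")
def geometry():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def phasing_volume():
    """Small noiseless volume for phase-retrieval tests: 16^3 particle,
    twofold oversampling -> 32^3 grid."""
    model = ParticleModel(grid_size=16, inradius=5.0, edge_softness=0.0,
                         core_radius=2.5)
    density = make_icosahedron_density(model)
    volume = ground_truth_intensity(density, 2.0)
    return density, volume


@pytest.fixture(scope="session")
def small_dataset():
    """240-pattern single/multi dataset with a 100-pattern labelled subset,
    preprocessed to classifier features.  Shared across classifier tests."""
    config = SimConfig(n_patterns=240, fraction_single=0.5, fraction_multi=0.5,
                       fraction_nonhit=0.0, rng_seed=7,
                       train_size=100, train_singles=40)
    stack, truth, volume = generate_dataset(config)
    photons, features = preprocess_stack(stack, stack.geometry.beam_center,
                                         gain=stack.geometry.gain)
    return {
        "stack": stack,
        "truth": truth,
        "volume": volume,
        "photons": photons,
        "features": features,
        "labels": truth.binary(),
        "train_idx": np.flatnonzero(truth.train_mask),
        "test_idx": np.flatnonzero(~truth.train_mask),
    }
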