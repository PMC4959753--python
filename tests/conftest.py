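import numpy as np
import pytest

import garnettrack as gt


@pytest.fixture(scope="session")
def coated_phantom():
    """A desk-scale coated packing with grains, plus its rendered gray volume.

    Shared by segmentation, distance and pipeline tests; treat as read-only.
    """
    spec = gt.PhantomSpec(
        shape=(96, 96, 96), aggregate_radius_range=(7, 12),
        n_grains=2, grain_radius_range=(14, 16),
        coat_coverage=0.02, max_particles=200, seed=11,
    )
    _, truth = gt.generate_packing(spec)
    truth = gt.coat_with_particles(truth)
    gray = gt.render_grayscale(truth)
    return spec, truth, gray


@pytest.fixture(scope="session")
def bare_packing():
    """An uncoated packing for compaction mass-balance checks."""
    spec = gt.PhantomSpec(shape=(96, 96, 96), aggregate_radius_range=(7, 12),
                          n_grains=0, seed=21)
    gray, truth = gt.generate_packing(spec)
    return spec, truth, gray


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_labels(rng, shape=(16, 16, 16), pore_frac=0.3):
    """Random label volume with connected pore seeded from a Bernoulli field."""
    labels = np.where(rng.random(shape) < pore_frac,
                      np.uint8(gt.ClassCode.PORE_CONNECTED),
                      np.uint8(gt.ClassCode.MATRIX))
    return gt.LabelVolume(labels, voxel_size=8.0)
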