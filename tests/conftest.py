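import numpy as np
import pytest

import cobbnet as cn


@pytest.fixture(scope="session")
def small_phantoms():
    """Forty noisy phantom radiographs with ground truth."""
    return cn.generate_dataset(40, seed=42)


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = cn.generate_spine_spec(seed=7)
    return cn.render_radiograph(spec, noise_level=0.0, seed=0)


@pytest.fixture(scope="session")
def tiny_patchset(small_phantoms):
    """40 radiographs x 17 vertebrae x 12 patches."""
    return cn.sample_training_patches(
        small_phantoms, patches_per_vertebra=12, jitter_radius=15.0, seed=3
    )


@pytest.fixture(scope="session")
def small_trained(tiny_patchset):
    """A model trained on the small protocol; accurate enough for
    end-to-end measurement tests (held-out MAE ~1 degree)."""
    model = cn.SlopeRegression(tiny_patchset, cn.TrainingConfig(seed=2))
    return model.fit()


@pytest.fixture(scope="session")
def random_patch_vectors():
    rng = np.random.default_rng(123)
    return rng.uniform(0.0, 1.0, size=(500, 2500))
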