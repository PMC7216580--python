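import numpy as np
import pytest

import methgen as mg


@pytest.fixture
def tiny_matrix():
    """3 samples x 3 CpGs with one missing entry."""
    vals = np.array([[0.1, 0.9, 0.5], [0.2, np.nan, 0.6], [0.3, 0.8, 0.7]])
    return mg.BetaMatrix(["s1", "s2", "s3"], ["cg1", "cg2", "cg3"], vals)


@pytest.fixture(scope="session")
def separable_fixture():
    """Two well-separated conditions, clean values, with ground truth."""
    spec = mg.SyntheticSpec(
        n_conditions=2,
        n_cpgs=20,
        n_samples_per_condition=60,
        mean_separation=0.4,
        frac_informative=1.0,
        concentration_range=(20.0, 40.0),
        seed=11,
    )
    return mg.generate_ground_truth(spec)


@pytest.fixture(scope="session")
def trained_small_cvae(separable_fixture):
    """A reduced CVAE trained on the separable two-condition fixture."""
    matrix, labels, _ = separable_fixture
    chunked = mg.chunk_cpgs(matrix, chunk_size=1000)
    cfg = mg.CVAEConfig(
        encoder_hidden=(16, 8), latent_dim=4, epochs=300, batch_size=40, seed=5
    )
    state = mg.train_cvae(chunked, labels, cfg)
    return state
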