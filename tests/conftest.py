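import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd_kernel(rng, m, p=None):
    """Full-rank-by-construction linear kernel of random features."""
    X = rng.normal(size=(m, p or m + 3))
    return X @ X.T


@pytest.fixture
def tiny_dataset():
    """Small well-separated two-modality dataset for fast end-to-end runs."""
    from kernelfuse.synthetic import ModalitySpec, SyntheticConfig, generate

    cfg = SyntheticConfig(
        n_per_class=6,
        modalities=(
            ModalitySpec("m1", 40, informative_fraction=0.25, effect_size=1.5),
            ModalitySpec("m2", 60, informative_fraction=0.25, effect_size=1.5),
            ModalitySpec("m3", 50, informative_fraction=0.25, effect_size=1.5),
        ),
        redundancy=0.0,
        seed=7,
    )
    return generate(cfg)
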