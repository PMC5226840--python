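import numpy as np
import pytest

from dielkit import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def grid():
    """The 48 h / 4 h sampling grid (ZT0..ZT44)."""
    return tuple(float(t) for t in range(0, 48, 4))


@pytest.fixture(scope="session")
def noiseless_cosine():
    """All-rhythmic cosine dataset with on-grid (4 h) phases, no noise."""
    spec = SyntheticSpec(
        n_genes=40,
        frac_rhythmic=1.0,
        shapes={"cosine": 1.0},
        noise_sd=0.0,
        phase_grid=4.0,
        seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def noise_only():
    """Pure-noise (arrhythmic) dataset of 300 genes."""
    spec = SyntheticSpec(
        n_genes=300, frac_rhythmic=0.0, noise_sd=0.5, seed=5
    )
    return generate_dataset(spec)
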