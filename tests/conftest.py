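import numpy as np
import pytest

from radsig.syndata import PhantomConfig, generate_phantom_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-patient phantom at default geometry, shared across tests."""
    return generate_phantom_cohort(PhantomConfig(n_patients=8, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_labelled_voi(rng, shape=(5, 5, 5), ng=4, fill=0.8):
    """Seeded random integer-labelled VOI with background holes."""
    lab = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    lab[rng.uniform(size=shape) > fill] = 0
    if not (lab > 0).any():
        lab[tuple(s // 2 for s in shape)] = 1
    return lab
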