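import numpy as np
import pytest

from mdakrls.data_model import AssociationDataset
from mdakrls.synthetic import SyntheticSpec, generate


@pytest.fixture
def identity_dataset():
    """2x2 dataset with A = I."""
    return AssociationDataset(("d1", "d2"), ("m1", "m2"), np.eye(2, dtype=int))


@pytest.fixture
def small_structured():
    """Small planted-block dataset with strong signal, cheap to cross-validate."""
    return generate(SyntheticSpec(nd=12, nm=30, n_blocks=3, p_in=0.5, p_out=0.02,
                                  hide_fraction=0.2, seed=7))


def random_binary(rng, nd, nm, density=0.4):
    return (rng.random((nd, nm)) < density).astype(int)
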