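import numpy as np
import pytest

from allokit import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def conformer_pair():
    """Synthetic pair: residue 5 displaced by (3,4,0) under a rigid motion."""
    return synthgen.make_conformer_pair(n_residues=20,
                                        displaced={5: (3.0, 4.0, 0.0)},
                                        seed=21)
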