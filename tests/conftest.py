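import numpy as np
import pytest

from tensorsel.datatypes import OmicsTensor, SampleDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_tensor(rng):
    return rng.normal(size=(6, 5, 4))


def make_designed_tensor(values):
    """Wrap a raw array in an OmicsTensor with a trivial design."""
    n, m, k = values.shape
    return OmicsTensor(
        values=values,
        feature_ids=[f"f{i}" for i in range(n)],
        mode2_ids=[f"r{j}" for j in range(m)],
        mode3_ids=[f"c{c}" for c in range(k)],
        design=SampleDesign(
            replicate_labels=[f"r{j}" for j in range(m)],
            condition_levels=[f"c{c}" for c in range(k)],
        ),
    )
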