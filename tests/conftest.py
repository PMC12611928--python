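import numpy as np
import pytest

from fusionpept import chimera, simulate


@pytest.fixture(scope="session")
def fusion_dataset():
    """Default synthetic fusion pair with planted truth."""
    seg5, seg3, truth = simulate.gen_fusion_pair(101)
    tx = chimera.build_fusion_transcript(seg5, seg3)
    return seg5, seg3, tx, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
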