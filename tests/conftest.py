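import numpy as np
import pytest

from asqpcr import datasets


@pytest.fixture
def detection_panel():
    return datasets.detection_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20314)
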