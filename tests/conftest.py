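import numpy as np
import pytest

from cmbayes import ConfusionMatrix


@pytest.fixture
def worked_cm() -> ConfusionMatrix:
    """The cocaine-purity classifier's published confusion matrix
    (TP=26, FN=0, FP=2, TN=6), the package's running worked example."""
    return ConfusionMatrix(tp=26, fn=0, fp=2, tn=6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
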