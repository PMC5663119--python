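import numpy as np
import pandas as pd
import pytest

from dysregdir import PairedExpressionStudy


@pytest.fixture
def tiny_study():
    """2 features x 3 subjects, one factor, hand-written values."""
    return PairedExpressionStudy(
        features=["fA", "fB"],
        subjects=["s1", "s2", "s3"],
        tumor_signal=np.array([[8.0, 0.0, 5.0], [1.0, 2.0, 3.0]]),
        normal_signal=np.array([[2.0, 0.0, 5.0], [4.0, 5.0, 6.0]]),
        site=np.array(["proximal", "proximal", "distal"], dtype=object),
        factors=pd.DataFrame({"F1": [0.0, 1.0, np.nan]}, index=["s1", "s2", "s3"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250906)
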