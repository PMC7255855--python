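import numpy as np
import pytest
from hypothesis import settings
from scipy.spatial import procrustes

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def procrustes_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two point configurations after optimal
    translation/rotation/scaling alignment."""
    m1, m2, _ = procrustes(np.asarray(a), np.asarray(b))
    return float(np.corrcoef(m1.ravel(), m2.ravel())[0, 1])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
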