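import numpy as np
import pytest

from spikedwt import AnalysisWindow, DWTConfig


@pytest.fixture
def window():
    """Default response window: 1.4 s, 128 bins, starting at t = 0 s."""
    return AnalysisWindow(start=0.0)


@pytest.fixture
def dwt_cfg(window):
    return DWTConfig(window=window)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def haar_matrix(n: int, levels: int) -> np.ndarray:
    """Explicit orthonormal Haar analysis matrix (independent oracle).

    Rows are ordered level 1 details, level 2 details, ..., approximation,
    each level in natural time order.  Built by cascading the pairwise
    (a-b)/sqrt(2), (a+b)/sqrt(2) filter bank on the identity.
    """
    detail_rows = []
    approx = np.eye(n)
    for _ in range(levels):
        a = approx
        approx = (a[0::2] + a[1::2]) / np.sqrt(2.0)
        detail_rows.append((a[0::2] - a[1::2]) / np.sqrt(2.0))
    return np.vstack(detail_rows + [approx])
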