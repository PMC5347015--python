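from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chillseq.model import CountMatrix

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def small_matrix() -> CountMatrix:
    """Three genes, two equal-depth libraries."""
    counts = np.array([[10, 40], [100, 100], [0, 8]], dtype=np.int64)
    return CountMatrix(
        ["g1", "g2", "g3"], ["A", "B"], counts, [1_000_000, 1_000_000]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
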