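import numpy as np
import pytest

from brainprg import synthetic as syn


@pytest.fixture(scope="session")
def small_geometry():
    """64 nodes, default cortex-scale box."""
    return syn.generate_positions(64, seed=101)


@pytest.fixture(scope="session")
def medium_geometry():
    """256 nodes for distance-resolved statistics."""
    return syn.generate_positions(256, seed=102)


@pytest.fixture(scope="session")
def edr_small(small_geometry):
    return syn.generate_edr_connectivity(small_geometry, gamma=0.106)


def batch_sem(series: np.ndarray, n_batches: int = 50) -> float:
    """Monte-Carlo standard error by batch means (robust to autocorrelation)."""
    series = np.asarray(series, dtype=float)
    m = series.size // n_batches
    if m < 1:
        return float(series.std(ddof=1) / np.sqrt(series.size))
    batches = series[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
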