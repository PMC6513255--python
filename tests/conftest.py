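import numpy as np
import pytest

from harpyrange import synthetic_data as sd


@pytest.fixture(scope="session")
def dataset64():
    """Default-condition synthetic dataset (64x64, 300 presences)."""
    return sd.make_dataset(sd.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """Small, fast dataset for pipeline-level tests."""
    cfg = sd.SyntheticConfig(seed=11, n_rows=48, n_cols=48, n_presences=120)
    return sd.make_dataset(cfg)


def morans_i(values: np.ndarray) -> float:
    """Lag-1 (rook neighbours) Moran's I of a 2-D field.

    Independent spatial-autocorrelation oracle: I close to 0 for white
    noise, positive for smoothed fields.
    """
    z = values - values.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    w = z[:, :-1].size + z[:-1, :].size  # number of (directed/2) neighbour pairs
    return float((z.size / w) * (num / (z**2).sum()))
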