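import numpy as np
import pandas as pd
import pytest

from betacoh.containers import EpochSet
from betacoh.timefreq import ComplexTFR


def make_tfr(values: np.ndarray, freqs=None, grid_ms=None, ch_names=None) -> ComplexTFR:
    """Wrap a raw complex array (trials, channels, freqs, grid) as a TFR."""
    values = np.asarray(values)
    n_t, n_c, n_f, n_g = values.shape
    freqs = np.asarray(freqs) if freqs is not None else np.arange(4.0, 4.0 + n_f)
    grid_ms = (
        np.asarray(grid_ms) if grid_ms is not None
        else 400.0 + 20.0 * np.arange(n_g)
    )
    ch_names = ch_names or [f"ch{i}" for i in range(n_c)]
    return ComplexTFR(
        values=values, freqs=freqs, grid_ms=grid_ms, ch_names=ch_names,
        edge_ok=np.ones((n_f, n_g), dtype=bool),
    )


def make_epochs(data: np.ndarray, rate: float = 500.0, t0_ms: float = 0.0) -> EpochSet:
    n_t, n_c, _ = data.shape
    return EpochSet(
        data=data, rate=rate, t0_ms=t0_ms,
        ch_names=[f"ch{i}" for i in range(n_c)],
        trial_meta=pd.DataFrame({"trial": np.arange(n_t)}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
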