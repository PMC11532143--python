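import numpy as np
import pytest
from hypothesis import settings

from fermfuse.model import BatchDataset, BatchMeta, SourceClass, TimeSeries

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_series(values, times=None, variable="x", source=SourceClass.ONLINE, unit=""):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    return TimeSeries(variable=variable, unit=unit, source=source,
                      times=np.asarray(times, dtype=float), values=values)


def make_batch(series_list, batch_id="b1", **meta):
    b = BatchDataset(meta=BatchMeta(batch_id=batch_id, **meta))
    for ts in series_list:
        b.add(ts)
    return b


@pytest.fixture
def tiny_batch():
    """Three-source batch with a 0.1 h online grid over 10 h."""
    grid = np.round(np.arange(0.0, 10.01, 0.1), 10)
    return make_batch([
        make_series(7.0 - 0.01 * grid, grid, "ph"),
        make_series(2.0 * grid + 1.0, grid, "do"),
        make_series([0.04, 0.041, 0.039, 0.04, 0.042],
                    [0.0, 2.5, 5.0, 7.5, 10.0], "co2_air", SourceClass.AT_LINE),
        make_series([1.0, 5.0, 9.0], [0.0, 4.0, 8.0], "biomass", SourceClass.OFFLINE),
    ])


@pytest.fixture(scope="session")
def noiseless_sim():
    """One noiseless simulated batch shared by round-trip tests."""
    from fermfuse.synth import SimConfig, simulate_batch

    return simulate_batch(SimConfig(noise_sigma={}, duration_h=12.0, seed=1))
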