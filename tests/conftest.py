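import numpy as np
import pandas as pd
import pytest

from dynagra import MonitoringPanel, RunConfig, WindowConfig


def make_panel(columns: dict, start="2016-07-11", n=None) -> MonitoringPanel:
    """Build a panel from {(station, variable): array} mappings."""
    n = n or len(next(iter(columns.values())))
    index = pd.date_range(start, periods=n, freq="h")
    frame = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()},
                         index=index)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["station", "variable"])
    frame.index.name = "timestamp"
    return MonitoringPanel(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20160711)


@pytest.fixture
def config():
    """Small explicit windows so short fixtures are analysable."""
    return RunConfig(window=WindowConfig(L0=10, Lmin=10, Lmax=24))


@pytest.fixture
def coupled_panel(rng):
    """Two-station panel: N1 tracks HS with noise, N2 is independent."""
    n = 120
    src = np.cumsum(rng.normal(0, 1, n)) * 0.1 + np.sin(np.arange(n) / 8.0)
    return make_panel({
        ("HS", "PM2.5"): src,
        ("N1", "PM2.5"): src + rng.normal(0, 0.05, n),
        ("N2", "PM2.5"): rng.normal(0, 1, n),
        ("HS", "CO"): 0.5 * src + rng.normal(0, 0.1, n),
    })
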