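import numpy as np
import pytest

from longiv.dgm import DGMParams, simulate
from longiv.panel_data import PanelData


@pytest.fixture(scope="session")
def default_params() -> DGMParams:
    return DGMParams()


@pytest.fixture(scope="session")
def strong_panel() -> "PanelData":
    """One moderately sized panel from the default mechanism (strong IV)."""
    return simulate(DGMParams(alpha=0.5), n=2000, seed=1234)


@pytest.fixture(scope="session")
def big_panel() -> "PanelData":
    """Large panel for asymptotic checks (shared across tests for speed)."""
    return simulate(DGMParams(alpha=0.5), n=100_000, seed=99)


@pytest.fixture
def tiny_panel() -> PanelData:
    """Deterministic K=1 panel used in closed-form examples."""
    return PanelData(
        Y=np.array([1.0, 2.0, 1.0, 2.0]),
        A=np.array([[0], [1], [0], [1]]),
        Z=np.array([[0], [1], [0], [1]]),
    )


def type7_quantile(values, p):
    """Independent order-statistic interpolation oracle (the 'type 7' rule)."""
    x = np.sort(np.asarray(values, dtype=float))
    h = (x.size - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, x.size - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])
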