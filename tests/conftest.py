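import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gsckit as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return g.SimConfig()


@pytest.fixture(scope="session")
def bulk_cohort(cfg):
    """27-sample bulk peak cohort with planted states (fixed seed)."""
    samples, truth = g.simulate_bulk_peaks(cfg, seed=101)
    return samples, truth


@pytest.fixture(scope="session")
def catalog(bulk_cohort):
    samples, _ = bulk_cohort
    return g.build_catalog(samples)


@pytest.fixture(scope="session")
def cell_data(cfg):
    """~1,000-cell matrix with planted cellular states and stem minority."""
    cells, truth = g.simulate_cell_matrix(cfg, seed=202)
    return cells, truth


@pytest.fixture(scope="session")
def cell_devs(cell_data):
    """Deviation scores for the four planted cellular-state signatures."""
    cells, truth = cell_data
    return {
        s: g.deviation_scores(
            cells, g.Signature(s, frozenset(regs.tolist())), n_background=50, seed=7
        )
        for s, regs in truth.state_signature_regions.items()
    }


@pytest.fixture(scope="session")
def expression(cfg):
    expr, truth = g.simulate_expression(cfg, seed=11)
    return expr, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
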