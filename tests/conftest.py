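import numpy as np
import pytest

from painlaw import Cohort, CohortSimConfig, PowerLawParams, TimeSeriesRecord, evaluate, generate_cohort

GRID = (0.0, 1.0, 6.0, 12.0)


def powerlaw_record(subject_id, prefactor, exponent, t0=1.0, grid=GRID, scale="geometric"):
    """Record lying exactly on a shifted power law."""
    params = PowerLawParams(prefactor, exponent, t0)
    return TimeSeriesRecord(subject_id, grid, tuple(evaluate(params, t) for t in grid), scale)


@pytest.fixture
def exact_record():
    return powerlaw_record("exact", 5.0, 0.4)


@pytest.fixture
def exact_cohort():
    """Noise-free cohort with heterogeneous prefactors, common exponent 0.3."""
    recs = [powerlaw_record(f"s{i}", 3.0 + 0.5 * i, 0.3) for i in range(10)]
    return Cohort(recs, GRID)


@pytest.fixture
def noisy_cohort():
    cohort, truth = generate_cohort(CohortSimConfig(seed=42, worsener_fraction=0.0))
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
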