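import numpy as np
import pytest

from kbplan.cohort import CohortConfig, generate_cohort
from kbplan.dvh import DVHCurve
from kbplan.pqm import default_criteria


@pytest.fixture
def ramp_curve():
    """Straight-line curve: full coverage at 0, gone by 20 Gy."""
    return DVHCurve("ramp", 60.0, np.array([0.0, 10.0, 20.0]), np.array([1.0, 0.5, 0.0]))


@pytest.fixture
def plateau_curve():
    """Full coverage up to 10 Gy, then a linear drop to zero at 20 Gy."""
    return DVHCurve("plateau", 10.0, np.array([0.0, 10.0, 20.0]), np.array([1.0, 1.0, 0.0]))


@pytest.fixture(scope="session")
def criteria():
    return default_criteria()


@pytest.fixture(scope="session")
def criteria_by_id(criteria):
    return {c.cid: c for c in criteria.criteria}


@pytest.fixture(scope="session")
def small_cohort():
    """Ten synthetic patients with planner-skill noise (seeded)."""
    return generate_cohort(CohortConfig(n_patients=10, seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Twenty best-effort synthetic patients (skill eps = 0, seeded)."""
    return generate_cohort(CohortConfig(n_patients=20, seed=7, sigma_eps=0.0))


def random_monotone_curve(rng: np.random.Generator, n: int = 30) -> DVHCurve:
    """A random strictly decreasing cumulative DVH for property tests."""
    dose = np.concatenate([[0.0], np.cumsum(rng.uniform(0.1, 3.0, size=n))])
    drops = rng.uniform(0.01, 1.0, size=n)
    rel = np.concatenate([[1.0], 1.0 - np.cumsum(drops) / drops.sum()])
    rel = np.clip(rel, 0.0, 1.0)
    rel[-1] = 0.0
    return DVHCurve("random", float(rng.uniform(10, 500)), dose, rel)
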