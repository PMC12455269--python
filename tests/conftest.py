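import numpy as np
import pytest
from hypothesis import settings

from amyspace.synthgen import CohortConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def pearson_oracle(x, y):
    """Independent Pearson implementation (direct formula, no shortcuts)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return num / den


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-subject exact-mode cohort on the default geometry, no 4D data."""
    cfg = CohortConfig(n_subjects=8, include_timeseries=False,
                       missing_counts={"cbf": 1})
    return generate_cohort(cfg, seed=11)
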