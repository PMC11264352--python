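import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

# reproducible property tests: no example database, fixed generation
settings.register_profile("repcost", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("repcost")

from repcost.capture_data import OccasionSet
from repcost.multistate_cmr import Params


@pytest.fixture
def occ5() -> OccasionSet:
    return OccasionSet.from_years(range(2000, 2005))


@pytest.fixture
def occ10() -> OccasionSet:
    return OccasionSet.from_years(range(2000, 2010))


def random_params(occ: OccasionSet, rng: np.random.Generator,
                  trap: bool = True) -> Params:
    """Random valid natural-scale parameter arrays, bounded away from the
    extremes so enumeration stays well-conditioned."""
    T = occ.n_occasions
    phi = rng.uniform(0.2, 0.95, size=(2, T - 1, 2))
    psi = rng.uniform(0.05, 0.6, size=(2, T - 1, 2))
    p = np.zeros((2, T, 2, 2))
    for t in range(T):
        if occ.resighting_active[t]:
            p[:, t, :, 1] = rng.uniform(0.2, 0.9, size=(2, 2))
            p[:, t, :, 0] = (rng.uniform(0.2, 0.9, size=(2, 2))
                             if trap else p[:, t, :, 1])
    return Params(phi=phi, p=p, psi=psi)
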