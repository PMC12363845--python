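import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles as `oracles`

from odorint.psychophysics import HillParams, RatingPoint, hill_intensity


@pytest.fixture
def hill100():
    return HillParams(imax=100.0, ec50=1e-6, n=1.5)


def make_ratings(params: HillParams, odorant_id="odor", n_points=9, noise_sd=0.0,
                 replicates=1, seed=0, decades=3.0):
    """Log-spaced ratings bracketing the curve's EC50."""
    rng = np.random.default_rng(seed)
    concs = params.ec50 * 10.0 ** np.linspace(-decades, decades, n_points)
    pts = []
    for rep in range(replicates):
        for c in concs:
            i = hill_intensity(params, c)
            if noise_sd:
                i = max(i + rng.normal(0, noise_sd), 0.0)
            pts.append(RatingPoint(odorant_id, float(c), float(i), rep))
    return pts


@pytest.fixture
def ratings_factory():
    return make_ratings


@pytest.fixture(scope="session")
def small_truth():
    """A small synthetic dataset shared by read-only tests."""
    from odorint.synthetic import generate_dataset

    return generate_dataset(
        seed=11, n_molecules=14, counts={2: 12, 3: 4}, component_pool=8
    )
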