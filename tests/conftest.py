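import numpy as np
import pytest

from reallife import (
    SolverConfig,
    build_dictionary,
    build_sparse_model,
    make_phantom,
)
from reallife.phantom import two_bundle_spec
from reallife.testing import identity_model, random_sparse_model  # noqa: F401 (re-exported for tests)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Canonical two-bundle phantom, no spurious fibers, no noise."""
    return make_phantom(two_bundle_spec(n_spurious=0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def candidate_phantom():
    """Two bundles + 5 spurious decoys, 1% noise (the pruning test-bed)."""
    return make_phantom(two_bundle_spec(n_spurious=5, noise_sigma=0.01, seed=7))


@pytest.fixture(scope="session")
def candidate_model(candidate_phantom):
    vol, c, _ = candidate_phantom
    dictionary = build_dictionary(vol.scheme)
    return build_sparse_model(c, vol, dictionary)


@pytest.fixture()
def tight_cfg():
    """Solver settings tight enough for oracle-level comparisons."""
    return SolverConfig(max_iters=5000, delta=1e-9, window=10)
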