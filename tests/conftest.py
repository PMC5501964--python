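import numpy as np
import pytest

from morphoconn import CohortSpec, generate_cohort

# small, fast study conditions reused across pipeline-level tests
SMALL_SPEC = dict(
    n_subjects=12,
    grid_shape=(16, 16, 16),
    n_rois=5,
    coupled_roi=3,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One small coupled cohort (12 subjects, 5 ROIs/hemisphere)."""
    spec = CohortSpec(coupling_strength=0.9, noise_sd=0.2, rng_seed=7, **SMALL_SPEC)
    return spec, generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
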