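import numpy as np
import pytest

import stemflex as sf


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort with rasterized sections."""
    cfg = sf.CohortConfig(counts={c: 6 for c in sf.CATEGORIES}, seed=42)
    return sf.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_frame():
    """Tidy trait frame from a noiseless, shear-free mech-only cohort."""
    cfg = sf.CohortConfig(counts={c: 12 for c in sf.CATEGORIES}, seed=7,
                          rasterize_sections=False)
    return sf.cohort_to_frames(sf.generate_cohort(cfg), morphometrics="analytic")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
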