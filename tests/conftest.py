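import numpy as np
import pytest

from plasmafp import cohort as cohort_mod
from plasmafp import preprocess as prep_mod


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete two-visit cohort configuration."""
    return cohort_mod.SimulationConfig(
        n_set1=320, n_set2=240, n_overlap=160, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cohort_mod.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    """Preprocessed fingerprints of both visits plus the pooled matrix."""
    x1, _ = prep_mod.preprocess_matrix(
        small_cohort.spectra[1], small_cohort.water
    )
    x2, _ = prep_mod.preprocess_matrix(
        small_cohort.spectra[2], small_cohort.water
    )
    from plasmafp.containers import SpectraMatrix

    pooled = SpectraMatrix(
        np.concatenate([x1.sample_ids, x2.sample_ids]),
        x1.grid,
        np.vstack([x1.absorbance, x2.absorbance]),
    )
    return {1: x1, 2: x2, "pooled": pooled}


@pytest.fixture(scope="session")
def grid():
    return 950.0 + 2.0 * np.arange(1051)
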