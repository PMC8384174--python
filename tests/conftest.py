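import numpy as np
import pytest

from nestmix.data_model import CountDataset, standardize
from nestmix.dm_density import fit_dm
from nestmix.synthetic_data import SimulationConfig, simulate_study


def child_seed(seed: int, i: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))


def standardized_counts(study) -> CountDataset:
    """Replace the plot covariates of a study's counts with z-scores."""
    d = study.counts
    z, _ = standardize(d.plot_covariates)
    return CountDataset(d.plot_ids, d.y, d.observed_mask, d.survey_covariates, z)


@pytest.fixture(scope="session")
def small_study():
    """One seeded synthetic study at a reduced size, for cheap smoke tests."""
    return simulate_study(SimulationConfig(M=30), 123)


@pytest.fixture(scope="session")
def default_study():
    """One seeded synthetic study at the full design (M = 100)."""
    return simulate_study(SimulationConfig(), 7)


@pytest.fixture(scope="session")
def default_fit(default_study):
    """Open N-mixture fit of the default study (shrub on detection)."""
    d = standardized_counts(default_study)
    return fit_dm(d, [], ["shrub_cover"], K=d.max_count() + 30,
                  n_starts=1, fix_gamma=0.0)
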