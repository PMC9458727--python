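import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from adcascade.model import load_fixture_params, solve_model
from adcascade.sigmoid import fit_sigmoid
from adcascade.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def full_cohort_params():
    return load_fixture_params("full_cohort")


@pytest.fixture(scope="session")
def lmci_ad_params():
    return load_fixture_params("lmci_ad")


@pytest.fixture(scope="session")
def lmci_ad_trajectory(lmci_ad_params):
    return solve_model(lmci_ad_params, s_eval=np.linspace(-10, 20, 301))


@pytest.fixture(scope="session")
def lmci_ad_sigmoids(lmci_ad_trajectory):
    """Population sigmoids fitted to the noiseless calibrated trajectories."""
    tr = lmci_ad_trajectory
    return {k: fit_sigmoid((tr.s_grid, tr.values[:, i])).params
            for i, k in enumerate("ATNC")}


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    """60 subjects, 5 visits, no noise: the parameter-recovery workhorse."""
    cfg = GeneratorConfig(seed=11, n_subjects=60, visits_range=(5, 5),
                          noise_sd={k: 0.0 for k in "ATNC"})
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """100 subjects, 3-5 visits, observation noise SD 0.03 (study defaults)."""
    cfg = GeneratorConfig(seed=42, n_subjects=100, visits_range=(3, 5))
    return generate_cohort(cfg)
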