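import numpy as np
import pytest

from sibamod import SimConfig, generate_cohort
from sibamod.pipeline import Hyperparams, fit_sibamod, make_split


@pytest.fixture(scope="session")
def small_cohort():
    """Two synthetic patients with default study conditions (seeded)."""
    cfg = SimConfig(n_patients=2, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_patient(small_cohort):
    """One patient fitted at (λ=1.6, ν=5), reused by structural tests."""
    records, truths = small_cohort
    patient = records[0]
    split = make_split(patient, seed=0)
    fitted = fit_sibamod(patient, Hyperparams(lam=1.6, nu=5), split, base_seed=0)
    return patient, split, fitted


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
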