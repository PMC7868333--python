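import numpy as np
import pytest

from catdev import eap_scores, fit_model, published_item_bank
from catdev.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def pub_bank():
    """The published 21-item graded-response bank excerpt."""
    return published_item_bank()


@pytest.fixture(scope="session")
def clean_cohort():
    """A defect-free 20-item mixed cohort (n=500) shared across tests."""
    spec = CohortSpec(seed=77, n_persons=500, n_dichotomous=6, n_polytomous=14)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def calibrated_clean(clean_cohort):
    """GRM calibration and EAP scores of the clean cohort."""
    bank, fit = fit_model(clean_cohort.responses, "GRM")
    thetas = eap_scores(clean_cohort.responses, bank)
    return bank, fit, thetas


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
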