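import pytest

from pvscreen import (
    default_config,
    default_confounder_catalog,
    default_drug_dictionary,
    default_seizure_term_set,
)
from pvscreen.vocabulary import SEIZURE_SET_NAME


@pytest.fixture(scope="session")
def dictionary():
    return default_drug_dictionary()


@pytest.fixture(scope="session")
def seizure_set():
    return default_seizure_term_set()


@pytest.fixture(scope="session")
def catalog():
    return default_confounder_catalog()


@pytest.fixture()
def small_config():
    """500-case stream with one strong planted signal and mild confounding."""
    return default_config(
        n_cases=500,
        seed=11,
        planted_lambda={"N06AX12": {SEIZURE_SET_NAME: 8.0}},
        confounded_pairs={"N06AB04": {"seizures_history": 0.05}},
        duplicate_rate=0.2,
    )
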