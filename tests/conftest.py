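import pytest
from hypothesis import settings

from dtsq import datasets, modeling

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

RSM_TERMS = {
    "accuracy": ["NS", "TD", "Tl"],
    "snr": ["NS", "Tl", "NS^2", "NS*Tl"],
    "tq": ["NS", "Tl", "NS^2", "Tl^2", "NS*Tl"],
}


@pytest.fixture(scope="session")
def pbd():
    return datasets.load_pbd()


@pytest.fixture(scope="session")
def ccd():
    return datasets.load_ccd()


@pytest.fixture(scope="session")
def rsm_models(ccd):
    return {r: modeling.fit_rsm(ccd, r, terms) for r, terms in RSM_TERMS.items()}
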