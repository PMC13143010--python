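import pytest

from pocus_cma import load_parameters, resolve_prevalence

#: published per-patient base-case costs (SGD), used as calibration anchors
TTE_BASE_PER_PATIENT = 1386.63
AIPOC_BASE_PER_PATIENT = 1175.18


@pytest.fixture(scope="session")
def paper_config():
    """The bundled published model inputs."""
    return load_parameters()


@pytest.fixture(scope="session")
def paper_params(paper_config):
    """Published inputs with prevalence calibrated on the TTE base case."""
    return resolve_prevalence(paper_config.params, paper_config.calibration)


@pytest.fixture(scope="session")
def quantile_fits(paper_config):
    return paper_config.fits("quantile")


@pytest.fixture(scope="session")
def moment_fits(paper_config):
    return paper_config.fits("moments")
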