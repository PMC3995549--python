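import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hdpk.pkdata import (
    Analyte,
    ConcentrationProfile,
    DialysisWindow,
    DoseEvent,
    Matrix,
    StudyConfig,
)
from hdpk.synthsim import SimParams, SimScenario


def make_profile(
    times,
    concs,
    bloq=None,
    subject="S01",
    analyte=Analyte.METABOLITE,
    matrix=Matrix.PLASMA,
    dose=2.5,
    lloq=2.0,
):
    return ConcentrationProfile(
        subject,
        analyte,
        matrix,
        times,
        concs,
        bloq,
        dose=DoseEvent(dose) if dose else None,
        lloq=lloq,
    )


@pytest.fixture
def config():
    return StudyConfig()


@pytest.fixture
def dialysis():
    return DialysisWindow()


@pytest.fixture
def noiseless_params():
    return SimParams(iiv_cv=0.0, residual_cv=0.0)


@pytest.fixture
def noiseless_scenario(noiseless_params):
    return SimScenario(params=noiseless_params, doses=(2.5,), n_subjects=1)


@pytest.fixture
def monoexp_profile():
    """Exact mono-exponential decay C(t) = 100*exp(-0.1 t)."""
    t = np.array([6.0, 12.0, 24.0, 48.0, 72.0])
    return make_profile(t, 100.0 * np.exp(-0.1 * t))
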