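import numpy as np
import pytest

from bystander_tgi import (
    AgeStructureParameters,
    DoseResponseParameters,
    PayloadParameters,
    TumorParameters,
)


@pytest.fixture
def payload_params():
    """Reference payload scenario: k_in=1/day, k=2, beta=0.7, C0=200 nM."""
    return PayloadParameters()


@pytest.fixture
def dr_params():
    """Reference Emax parameters: E0=120 nM, Emax=0.6931, IC50=300 nM, Hill 1."""
    return DoseResponseParameters()


@pytest.fixture
def tumor_params():
    """Reference tumor: c=4.6e-3/(nM day), lam=0.5/day, T0=1000, Tmax=2e4, logistic."""
    return TumorParameters()


@pytest.fixture
def tumor_exponential():
    return TumorParameters(growth_form="exponential")


@pytest.fixture
def age_params():
    return AgeStructureParameters()


@pytest.fixture
def short_grid():
    return np.linspace(0.0, 30.0, 301)


@pytest.fixture
def tgi_grid():
    return np.linspace(0.0, 60.0, 601)
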