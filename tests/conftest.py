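import warnings

import pytest

from popkarc import (
    PopulationModel,
    fit,
    generate_population,
    simulate_trial,
)


@pytest.fixture(scope="session")
def ref_model():
    """Published final estimates (typical CL/V, age exponent, IIV, residual)."""
    return PopulationModel.infant_arc_reference()


@pytest.fixture(scope="session")
def study_dataset(ref_model):
    """One synthetic study-scale trial: 20 ARC infants, sparse sampling."""
    pop = generate_population(20, seed=10)
    return simulate_trial(pop, ref_model, seed=11)


@pytest.fixture(scope="session")
def study_fit(study_dataset, ref_model):
    """Full fit (with covariance) of the study-scale trial, shared across
    evaluation tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(study_dataset, ref_model)
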