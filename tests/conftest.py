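import numpy as np
import pytest

from intakequant import GeneratorConfig, fit, generate_intervention_study


@pytest.fixture(scope="session")
def default_study():
    """One deterministic draw of the default three-arm synthetic study."""
    return generate_intervention_study(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def small_fitted_model(default_study):
    """A modest but usable fit shared across prediction/io/plot tests."""
    data, _ = default_study
    return fit(data, niter=1500, burnin=500, seed=202)
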