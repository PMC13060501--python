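import numpy as np
import pytest

import poppk


@pytest.fixture(scope="session")
def truth():
    """Published final parameter estimates used as generative truth."""
    return poppk.published_parameters()


@pytest.fixture(scope="session")
def design():
    return poppk.default_design()


@pytest.fixture(scope="session")
def dataset(design, truth):
    """One replicate of the default sparse design at the published truth."""
    return poppk.simulate_dataset(design, truth, seed=3)


@pytest.fixture(scope="session")
def fast_settings():
    """Single-restart settings for replicate sweeps."""
    return poppk.FitSettings(n_restarts=1)


@pytest.fixture(scope="session")
def fitted(dataset, fast_settings):
    """Final-model fit of the session dataset (shared; fits are costly)."""
    return poppk.fit_model(dataset, with_dose_covariate=True,
                           settings=fast_settings)
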