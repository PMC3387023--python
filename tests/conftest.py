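import numpy as np
import pytest

import vpchange as vp


@pytest.fixture(scope="session")
def eeo_params():
    return {"J_low": 15.142857142857142, "J_high": 29.285714285714285,
            "p_change": 0.5}


@pytest.fixture(scope="session")
def small_eeo_dataset(eeo_params):
    """400 trials with responses from an equal-precision optimal observer."""
    trials = vp.generate_trials(400, np.random.default_rng(42))
    return vp.simulate_responses(trials, vp.parse_model_code("EEO"),
                                 eeo_params, seed=43)
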