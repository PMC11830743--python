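"""Shared fixtures.

The trained harness model is expensive (minutes of CPU), so it is built
once per session and shared by every test that needs a trained encoder.
"""

import numpy as np
import pytest


@pytest.fixture(scope="session")
def trained_harness():
    """Seeded reference harness: slim booster VAE trained on 2000 phantoms
    downsampled to 64 x 64.  Returns (model, history)."""
    from gclspace import harness

    model, history, _ = harness.train_harness_model(seed=0, n_maps=2000)
    return model, history


@pytest.fixture(scope="session")
def harness_eval_phantoms(trained_harness):
    """Held-out mixed-pattern phantoms (severity >= 0.7) plus their codes."""
    from gclspace import harness

    model, _ = trained_harness
    phantoms = harness.make_eval_phantoms(seed=9910, n=200)
    codes = harness.encode_eval_phantoms(model, phantoms)
    return phantoms, codes


@pytest.fixture(scope="session")
def longitudinal_cohort():
    from gclspace import phantom

    series, _ = phantom.make_cohort(phantom.longitudinal_cohort_spec(60), seed=17)
    return series
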