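import numpy as np
import pytest

import spikesig as sg


@pytest.fixture(scope="session")
def archetypal_features():
    """Featurized archetypal cohort at the reference sizes (25/20/20/20)."""
    cohort, labels = sg.generate_archetypal_cohort(seed=101)
    return [sg.featurize(t) for t in cohort], labels


@pytest.fixture(scope="session")
def selection_features():
    """Featurized cohort large enough for the 12-split selection protocol."""
    cohort, labels = sg.generate_archetypal_cohort(
        {"control": 33, "ataxia": 24, "dystonia": 24, "tremor": 24}, seed=7)
    return [sg.featurize(t) for t in cohort], labels


@pytest.fixture()
def regular_train():
    """Perfectly regular 30-s spike train with an exactly representable
    period (2**-6 s = 15.625 ms, 64 spikes/s), so ISIs are float-exact."""
    ts = np.arange(1, 1921) * 0.015625 - 0.0078125
    return sg.SpikeTrain("regular64", ts, duration=30.0)
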