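import numpy as np
import pytest

from gaitstab.synthetic import (CohortSpec, simulate_classification_cohort,
                                simulate_trunk_acceleration)
from gaitstab.types import GaitEvents


@pytest.fixture(scope="session")
def spec():
    return CohortSpec(seed=0)


@pytest.fixture(scope="session")
def cohort(spec):
    """Default synthetic classification cohort (71 PwS / 39 HC, d=0.7)."""
    features, truth, _ = simulate_classification_cohort(spec)
    return features, truth


@pytest.fixture()
def clean_signal():
    """Noiseless, jitter-free periodic trunk signal with ground-truth events."""
    sig = simulate_trunk_acceleration(stride_freq=1.0, n_strides=20, fs=100.0,
                                      seed=0, jitter=0.0, noise_sd=0.0)
    ic = np.round(np.asarray(sig.meta["ic_times"]) * sig.fs).astype(int)
    to = np.round(np.asarray(sig.meta["to_times"]) * sig.fs).astype(int)
    events = GaitEvents(ic_indices=ic, to_indices=to, fs=sig.fs)
    return sig, events
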