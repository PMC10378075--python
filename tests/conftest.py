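import numpy as np
import pytest

from kymovoice.modeling import split_dataset
from kymovoice.simulate import (
    CohortSpec,
    SimulationParams,
    cohort_features,
    generate_cohort,
    generate_gww,
)


@pytest.fixture(scope="session")
def periodic_gww():
    """Perfectly periodic 250 Hz waveform: 3200 fps, 2000 frames (625 ms)."""
    params = SimulationParams(f0_hz=250.0, fps=3200.0, n_frames=2000, seed=0)
    gww, truth = generate_gww(params)
    return gww, truth


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature table of a small three-group cohort with a 70/30 split."""
    spec = CohortSpec(counts={"normophonic": 40, "benign": 40, "malignant": 40},
                      seed=11)
    feats = cohort_features(generate_cohort(spec), on_error="skip")
    return split_dataset(feats, train_fraction=0.7, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
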