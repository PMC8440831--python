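import numpy as np
import pytest

from spinemc.model import average_models
from spinemc.pipeline import lowpass_filter
from spinemc.synth import (
    GeometryParams,
    MotionSpec,
    OperatorVariabilitySpec,
    emulate_operators,
    generate_flexion_trial,
    generate_spine_model,
)


@pytest.fixture(scope="session")
def model():
    mdl, _ = generate_spine_model(GeometryParams(), seed=1)
    return mdl


@pytest.fixture(scope="session")
def model_record():
    return generate_spine_model(GeometryParams(), seed=1)[1]


@pytest.fixture(scope="session")
def clean_trial(model):
    """Noise-free 100-frame flexion trial with its ground truth."""
    return generate_flexion_trial(
        model, MotionSpec(n_frames=100, marker_noise_sd=0.0), seed=2)


@pytest.fixture(scope="session")
def noisy_trial(model):
    """Short realistic trial (0.5 mm marker noise) with its ground truth."""
    return generate_flexion_trial(model, MotionSpec(n_frames=60), seed=3)


@pytest.fixture(scope="session")
def operator_study():
    """Three subjects x three operators, with per-subject baselines."""
    subjects = []
    baselines = []
    for s in range(3):
        mdl, _ = generate_spine_model(GeometryParams(), seed=10 + s)
        ops = emulate_operators(mdl, OperatorVariabilitySpec(), 3,
                                seed=20 + s)
        subjects.append(ops)
        baselines.append(average_models(ops))
    return subjects, baselines


@pytest.fixture(scope="session")
def mc_inputs(operator_study):
    """Baseline + filtered trial for the first synthetic subject."""
    _, baselines = operator_study
    base = baselines[0]
    trial, truth = generate_flexion_trial(base, MotionSpec(n_frames=50),
                                          seed=30)
    return base, lowpass_filter(trial, 6.0), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
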