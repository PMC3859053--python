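import numpy as np
import pytest

from arhar import synthetic_data as sd
from arhar.ar_model import ARModel, simulate_ar
from arhar.signal_io import AccelerometerRecording


@pytest.fixture()
def simple_recording():
    """A 200-sample, 20 Hz unlabeled recording with mild structure."""
    rng = np.random.default_rng(7)
    n = 200
    t = np.arange(n) / 20.0
    return AccelerometerRecording(
        timestamps=t,
        x=np.sin(2 * np.pi * 1.5 * t) + 0.1 * rng.standard_normal(n),
        y=np.cos(2 * np.pi * 0.8 * t) + 0.1 * rng.standard_normal(n),
        z=9.81 + 0.1 * rng.standard_normal(n),
        sampling_rate=20.0,
        activity_label="walking",
        position_label="front-pocket-left",
        subject_id="subj00",
    )


@pytest.fixture(scope="session")
def default_profiles():
    return sd.make_default_profiles(order=10, seed=1)


@pytest.fixture(scope="session")
def walking_profile(default_profiles):
    return next(p for p in default_profiles if p.activity_name == "walking")


def ar_series(coefficients, n, seed, sigma2=1.0):
    """Simulate a stationary AR series with the given predictor coefficients."""
    model = ARModel(
        order=len(coefficients),
        coefficients=np.asarray(coefficients, dtype=float),
        innovation_variance=sigma2,
    )
    return simulate_ar(model, n, seed=seed)


@pytest.fixture(scope="session")
def small_corpora():
    """Compact train/eval corpora (disjoint subjects) for pipeline tests."""
    train = sd.generate_dataset(
        sd.GeneratorConfig(n_subjects=2, session_seconds=15.0, seed=5)
    )
    evaluation = sd.generate_dataset(
        sd.GeneratorConfig(n_subjects=1, first_subject=2, session_seconds=15.0, seed=5)
    )
    return train, evaluation
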