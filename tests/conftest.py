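import pytest
from hypothesis import HealthCheck, settings

from pdsense import (
    CAFConfig,
    activity_scene,
    breathing_scene,
    generate_experiment_corpus,
    process_recording,
)
from pdsense.activity import build_feature_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def breathing_bundle():
    """One default 15 bpm / 40 cm breathing scene with its spectrogram."""
    ref, surv = breathing_scene(rate_bpm=15.0, seed=1234)
    spec = process_recording(ref, surv, CAFConfig.breathing())
    return {"ref": ref, "surv": surv, "spec": spec}


@pytest.fixture(scope="session")
def walking_bundle():
    ref, surv = activity_scene(label="walking", seed=77)
    spec = process_recording(ref, surv, CAFConfig.activity())
    return {"ref": ref, "surv": surv, "spec": spec}


@pytest.fixture(scope="session")
def small_corpus():
    """2 subjects x 3 repetitions x 6 activities, windowed and ready."""
    entries = generate_experiment_corpus(
        {"activities": 6, "repetitions": 3, "subjects": 2}, seed=2024
    )
    return build_feature_corpus(entries)
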