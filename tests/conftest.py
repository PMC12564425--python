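import pytest
from hypothesis import HealthCheck, settings

from micard import (
    JitterModel,
    MatchTolerance,
    build_mic_pair,
    generate_batches,
    make_template_pair,
)

settings.register_profile(
    "micard",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("micard")


@pytest.fixture(scope="session")
def tol():
    return MatchTolerance()


@pytest.fixture(scope="session")
def jitter_only():
    """Default jitter sigmas, no dropout: the MIC-building study conditions."""
    return JitterModel(seed=7, dropout_rate=0.0)


@pytest.fixture(scope="session")
def pair40(jitter_only):
    """40 shared + 120 specific ions per species, 10 batches each, cards built."""
    tpl_a, tpl_b = make_template_pair(40, 120, seed=7, names=("GR", "PR"))
    batches_a = generate_batches(tpl_a, jitter_only, 10)
    batches_b = generate_batches(tpl_b, jitter_only, 10)
    mic_a, mic_b = build_mic_pair(batches_a, batches_b)
    return {
        "tpl_a": tpl_a,
        "tpl_b": tpl_b,
        "batches_a": batches_a,
        "batches_b": batches_b,
        "mic_a": mic_a,
        "mic_b": mic_b,
    }


@pytest.fixture(scope="session")
def canonical(jitter_only):
    """The canonical two-species study: 340 shared + 260 specific, 10 batches."""
    tpl_a, tpl_b = make_template_pair(340, 260, seed=1, names=("GR", "PR"))
    jm = JitterModel(seed=1, dropout_rate=0.0)
    batches_a = generate_batches(tpl_a, jm, 10)
    batches_b = generate_batches(tpl_b, jm, 10)
    mic_a, mic_b = build_mic_pair(batches_a, batches_b)
    return {
        "tpl_a": tpl_a,
        "tpl_b": tpl_b,
        "jm": jm,
        "mic_a": mic_a,
        "mic_b": mic_b,
    }
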