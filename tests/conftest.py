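import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """A small deterministic world shared by read-level tests."""
    from orphan_transcripts import make_world

    return make_world(seed=11, n_genes=12, n_novel=5, hidden_fraction=0.1)
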