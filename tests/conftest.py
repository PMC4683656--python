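import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "bcenmap",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("bcenmap")


@pytest.fixture(scope="session")
def library():
    from bcenmap.repeatscape import build_repeat_library

    return build_repeat_library(seed=1)


@pytest.fixture(scope="session")
def small_layout(library):
    """A compact centromere with 8 planted insertions."""
    from bcenmap.repeatscape import simulate_centromere

    return simulate_centromere(
        library, 8, seed=7, backbone_bp=8_000, n_b_blocks=2,
        band_sizes=[150, 200, 250, 300, 180, 220, 260, 340],
    )


@pytest.fixture(scope="session")
def experiment():
    """One full end-to-end synthetic experiment (seed 11)."""
    from bcenmap.pipeline import run_experiment

    return run_experiment(11)


@pytest.fixture(scope="session")
def published_matrix():
    from bcenmap.deletion_map import PresenceMatrix

    return PresenceMatrix.from_published_table()
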