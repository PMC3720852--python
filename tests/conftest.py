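import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome():
    """A 200 kb genome with the full 34-gene motility locus and one flagellin."""
    import flagmet as fm

    genome, features = fm.make_genome(
        "testsp", 200_000, fm.DEFAULT_LOCUS_SPEC, seed=11,
        dispersed_genes=[("fliC", 900)])
    return genome, features
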