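import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced two-genome mixture: host-like low GC/depth, symbiont-like
    high depth with overlapping GC. Small enough to regenerate in seconds."""
    from blobsep.synthetic_data import GenomeSpec, MixtureSpec, build_fixture

    spec = MixtureSpec(
        genomes=(
            GenomeSpec("host", 40_000, 0.25, 20.0, "Spirurida"),
            GenomeSpec("symbiont", 10_000, 0.32, 150.0, "Rickettsiales"),
        ),
        contig_mean_length=1000,
        hit_accuracy=1.0,
        seed=7,
    )
    return build_fixture(
        spec, tmp_path_factory.mktemp("small_bundle"),
        target_labels=["symbiont"], counter_labels=["host"],
    )
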