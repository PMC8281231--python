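import pytest

from foldscan import build_benchmark_spec, generate
from foldscan.synthetic_genome import (
    FeatureSpec,
    RepeatSpec,
    SyntheticSpec,
)


@pytest.fixture(scope="session")
def benchmark_bundle():
    """The default study-conditions bundle (seed 0)."""
    return generate(build_benchmark_spec(seed=0))


@pytest.fixture(scope="session")
def small_bundle():
    """A compact two-chromosome genome with a handful of planted repeats
    and both feature-placement modes, for fast pipeline-level tests."""
    spec = SyntheticSpec(
        chrom_lengths={"cA": 120_000, "cB": 80_000},
        background_gc=0.41,
        repeat_specs=[
            RepeatSpec("cA", 10_000, "CGG", 12),
            RepeatSpec("cA", 10_200, "CGG", 8),
            RepeatSpec("cA", 40_000, "AAT", 20),
            RepeatSpec("cA", 70_000, "AT", 25),
            RepeatSpec("cB", 5_000, "CGG", 30),
            RepeatSpec("cB", 50_000, "TTA", 9),
        ],
        feature_specs=[
            FeatureSpec("near", count=40, length=400, placement="near_repeats",
                        distance=800),
            FeatureSpec("unif", count=40, length=400, placement="uniform"),
        ],
        seed=11,
    )
    return generate(spec)
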