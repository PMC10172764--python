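import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zflipon.segmenter import SegmenterConfig, train
from zflipon.synthetic import SyntheticSpec, generate

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb synthetic contig with oracle truth labels (fast fixture)."""
    return generate(SyntheticSpec(contig_length=20_000, n_z_segments=40, seed=3))


@pytest.fixture(scope="session")
def tiny_ensemble(small_genome):
    """A small trained ensemble for interpretability/mutagenesis tests.

    Three folds and a 128-token window keep training to about a minute while
    still learning the Z-repeat vocabulary well enough for qualitative
    checks (attention enrichment, substitution effects).
    """
    g = small_genome
    cfg = SegmenterConfig(
        epochs=25,
        max_learning_rate=3e-3,
        n_folds=3,
        window=128,
        d_model=32,
        n_layers=2,
        n_heads=4,
        seed=5,
    )
    return train([g.sequence], {g.sequence.name: g.truth}, g.truth_intervals, cfg)


@pytest.fixture(scope="session")
def bench_genome():
    """The benchmark condition: 100 kb contig, 200 planted Z segments."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
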