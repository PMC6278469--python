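import numpy as np
import pytest

from efolearn import DescriptorTable, SyntheticSpec, generate


@pytest.fixture
def tiny_table() -> DescriptorTable:
    """Handmade 8x3 table with both classes present."""
    rng = np.random.default_rng(42)
    return DescriptorTable(
        instance_ids=[f"r{i}" for i in range(8)],
        descriptor_names=["a", "b", "c"],
        values=rng.normal(size=(8, 3)),
        labels=np.array([1, 0, 0, 1, 0, 0, 0, 1]),
    )


@pytest.fixture(scope="session")
def small_planted():
    """200x8 table with 3 strongly informative descriptors and clean labels."""
    spec = SyntheticSpec(
        n_instances=200,
        n_descriptors=8,
        n_positive=30,
        informative=(0, 1, 2),
        effect_size=2.0,
        label_noise=0.0,
        seed=5,
    )
    return generate(spec)


def random_ranking(rng, n_max=50, require_positive=True):
    """A random Ranking over at most n_max instances (helper for oracles)."""
    from efolearn import rank_scores

    n = int(rng.integers(2, n_max + 1))
    labels = rng.integers(0, 2, size=n)
    if require_positive and labels.sum() == 0:
        labels[int(rng.integers(0, n))] = 1
    scores = rng.normal(size=n)
    ids = [str(i) for i in range(n)]
    return rank_scores(ids, scores, labels)
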