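import numpy as np
import pytest

from dmftbiome import FeatureTable, SampleMetadata, TaxonomyMap
from dmftbiome.synth import SyntheticDesign, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [5, 0, 3, 2],
            [0, 7, 1, 0],
            [4, 4, 0, 9],
        ]
    )
    return FeatureTable(counts, ("s1", "s2", "s3"), ("t1", "t2", "t3", "t4"))


@pytest.fixture
def random_table_factory(rng):
    def make(n_samples=20, n_taxa=50, depth=500, zero_frac=0.3):
        p = rng.dirichlet(np.full(n_taxa, 0.4), size=n_samples)
        counts = np.vstack([rng.multinomial(depth, pi) for pi in p])
        mask = rng.random(counts.shape) < zero_frac
        counts = np.where(mask, 0, counts)
        counts[counts.sum(axis=1) == 0, 0] = 1
        return FeatureTable(
            counts,
            tuple(f"s{i}" for i in range(n_samples)),
            tuple(f"t{j}" for j in range(n_taxa)),
        )

    return make


@pytest.fixture
def simple_taxonomy():
    # four taxa, two sharing a genus
    return TaxonomyMap(
        {
            "t1": ("Bacteria", "P1", "C1", "O1", "F1", "Prevotella"),
            "t2": ("Bacteria", "P1", "C1", "O1", "F1", "Prevotella"),
            "t3": ("Bacteria", "P2", "C2", "O2", "F2", "Rothia"),
            "t4": ("Bacteria", "P2", "C2", "O2", "F3", ""),
        }
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort shared by read-only tests."""
    return generate_dataset(SyntheticDesign(seed=7))


def make_metadata(categories: dict) -> SampleMetadata:
    """Metadata with one representative DMFT score per requested category."""
    score_for = {"healthy": 0, "low": 2, "medium": 5, "high": 9, "extremely_high": 15}
    return SampleMetadata.from_scores(
        {sid: score_for[cat] for sid, cat in categories.items()}
    )
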