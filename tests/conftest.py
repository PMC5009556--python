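import numpy as np
import pandas as pd
import pytest

from cogsyn import (
    ExpressionStudy,
    GeneSet,
    GeneSetCollection,
    SampleInfo,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """3 genes x 4 samples (2 drugs at one dose each, 1 DMSO control)."""
    values = pd.DataFrame(
        {
            "S1": [1.0, 5.0, 2.0],
            "S2": [2.0, 6.0, 2.0],
            "S3": [3.0, 4.0, 2.0],
            "DMSO": [1.0, 5.0, 2.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    samples = [
        SampleInfo("S1", "drugA", "1", False),
        SampleInfo("S2", "drugB", "1", False),
        SampleInfo("S3", "drugC", "1", False),
        SampleInfo("DMSO", "DMSO", "0", True),
    ]
    return ExpressionStudy(values=values, samples=samples)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    sets = [
        GeneSet("SA", frozenset({"g1", "g2"})),
        GeneSet("SB", frozenset({"g2", "g3"})),
        GeneSet("SC", frozenset({"g1", "g2", "g3"})),
    ]
    return GeneSetCollection(sets=sets, universe=frozenset({"g1", "g2", "g3"}))


@pytest.fixture(scope="session")
def small_simulation():
    """A small but non-trivial simulated study shared across tests."""
    cfg = SimulationConfig(
        seed=7, n_genes=400, n_sets=20, set_size_range=(8, 12),
        n_drugs=4, sets_per_drug=6, overlap_step=3, b_permutations=100,
    )
    study, coll, truth = simulate_study(cfg)
    return cfg, study, coll, truth


def make_rank_permutation(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.permutation(n) + 1
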