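import numpy as np
import pandas as pd
import pytest

from bgconserve import Phylogeny, TraitTable, sim_tree


@pytest.fixture
def balanced4() -> Phylogeny:
    """((A:1,B:1):1,(C:1,D:1):1) — the workhorse hand-calculation tree."""
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def yule_factory():
    def make(n_tips: int, seed: int = 0) -> Phylogeny:
        return sim_tree(n_tips, model="yule", seed=seed)

    return make


@pytest.fixture
def small_table() -> TraitTable:
    counts = pd.DataFrame(
        {
            "NRPS": [0, 1, 5, 0],
            "Terpene": [2, 2, 0, 1],
        },
        index=["A", "B", "C", "D"],
    )
    meta = pd.DataFrame(
        {
            "dataset": ["plant_isolate"] * 4,
            "genus": ["g1", "g1", "g2", "g2"],
        },
        index=counts.index,
    )
    return TraitTable(counts, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
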