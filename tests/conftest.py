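import numpy as np
import pandas as pd
import pytest

from casingsoil import SimDesign, simulate_dataset
from casingsoil.io import CountTable


@pytest.fixture(scope="session")
def small_dataset():
    """2 groups x 3 stages x 2 replicates, 60 taxa: fast but structured."""
    design = SimDesign(
        n_taxa_pool=60, groups=(0, 100), stages=3, replicates=2,
        depth=2000, selection_strength=30.0, trait_signal=0.1,
        dispersal_regime="neutral", stage_amplitude=1.0, seed=1,
    )
    table, tree, meta, optima = simulate_dataset(design)
    return design, table, tree, meta, optima


@pytest.fixture(scope="session")
def study_dataset():
    """The full emulated study design: 5 groups x 6 stages x 3 replicates."""
    design = SimDesign(
        selection_strength=30.0, trait_signal=0.1,
        dispersal_regime="neutral", seed=42,
    )
    table, tree, meta, optima = simulate_dataset(design)
    return design, table, tree, meta, optima


@pytest.fixture()
def toy_table():
    return CountTable(
        pd.DataFrame(
            [[5, 2, 1, 1], [1, 1, 1, 1], [10, 0, 0, 0]],
            index=["s1", "s2", "s3"],
            columns=["t1", "t2", "t3", "t4"],
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
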