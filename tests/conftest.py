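import numpy as np
import pandas as pd
import pytest

from dietbiome import simulate


@pytest.fixture(scope="session")
def small_cohort():
    """60-person cohort with default planted effects; shared read-only."""
    return simulate.simulate_cohort(
        60, seed=11, n_items=60, n_otus=60, depth_range=(2000, 4000)
    )


@pytest.fixture(scope="session")
def covariates():
    return simulate.generate_covariates(80, seed=3)


@pytest.fixture(scope="session")
def food_db():
    return simulate.generate_food_database(60, seed=4)


@pytest.fixture(scope="session")
def recalls(covariates, food_db):
    return simulate.generate_recalls(covariates, food_db, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_tree_table():
    """Three-leaf tree and two tiny samples used in worked examples."""
    from dietbiome.tree import parse_newick

    tree = parse_newick("((L1:1,L2:1):1,L3:2);")
    table = pd.DataFrame(
        [[10, 0, 0], [0, 0, 10]], index=["A", "B"], columns=["L1", "L2", "L3"]
    )
    return tree, table
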