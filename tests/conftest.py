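import numpy as np
import pandas as pd
import pytest

import msetkit as mk


@pytest.fixture(scope="session")
def small_universe() -> mk.Universe:
    return mk.simulate_universe(mk.UniverseSpec(n_genes=1000, n_tf=100, seed=1))


@pytest.fixture(scope="session")
def de_study(small_universe):
    """A 1000-gene two-group study with 100 planted DE genes."""
    expr, truth = mk.simulate_expression(
        small_universe,
        mk.DeSpec(n_per_group=6, n_de=100, effect_log2=1.0, noise_sd_log2=0.25, seed=7),
    )
    return expr, truth


@pytest.fixture()
def tiny_expr() -> mk.ExpressionMatrix:
    """Hand-built 3-gene, 2x3-sample matrix with known group means."""
    values = pd.DataFrame(
        {
            "a1": [3.0, 5.0, 2.0],
            "a2": [3.1, 5.2, 2.0],
            "a3": [2.9, 4.8, 2.0],
            "b1": [2.0, 5.1, 2.0],
            "b2": [2.1, 4.9, 2.0],
            "b3": [1.9, 5.0, 2.0],
        },
        index=["UP2X", "FLAT", "CONST"],
    )
    groups = pd.Series(
        ["postpartum"] * 3 + ["virgin"] * 3, index=values.columns
    )
    return mk.ExpressionMatrix(values, groups)


def make_collection(*memberships: tuple[str, list[str]]) -> mk.DatabaseCollection:
    return mk.DatabaseCollection(
        [mk.GeneSet(name, frozenset(genes)) for name, genes in memberships]
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
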