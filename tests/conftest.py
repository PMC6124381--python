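import numpy as np
import pandas as pd
import pytest

import balancekit as bk


@pytest.fixture(scope="session")
def expenditures() -> bk.CompositionTable:
    return bk.load_fixture("expenditures")


@pytest.fixture(scope="session")
def expenditures_sbp() -> bk.SbpMatrix:
    return bk.load_fixture("expenditures_sbp")


def random_composition(rng, n, D, labels=None) -> bk.CompositionTable:
    """Lognormal positive table with labeled rows/columns."""
    if labels is None:
        labels = [f"c{j + 1}" for j in range(D)]
    values = np.exp(rng.normal(0.0, 1.0, size=(n, D)))
    df = pd.DataFrame(values, index=[f"s{i + 1}" for i in range(n)],
                      columns=labels)
    return bk.validate_composition(df)


def random_sbp(rng, D, labels=None) -> bk.SbpMatrix:
    """SBP of a random binary merge tree over D components."""
    if labels is None:
        labels = [f"c{j + 1}" for j in range(D)]
    return bk.tree_to_sbp(bk.random_merge_tree(labels, rng))
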