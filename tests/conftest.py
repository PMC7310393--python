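import numpy as np
import pandas as pd
import pytest

from amaci import Pedigree


def make_phenotypes(rows):
    """Build a phenotype table from (animal, population, sex, herd, cg, dam,
    value) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["animal", "population", "sex", "herd", "contemporary_group",
                 "dam", "value"],
    )
    df["extra_random_level"] = ""
    return df


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int = None):
    """Random acyclic pedigree; parents drawn among earlier animals."""
    if n_founders is None:
        n_founders = max(3, n // 8)
    rows = []
    for i in range(n):
        if i < n_founders:
            rows.append((f"a{i}", "", "", 1970, ""))
        else:
            s = f"a{rng.integers(0, i)}"
            d = f"a{rng.integers(0, i)}"
            if s == d:
                d = ""
            if rng.random() < 0.1:
                s = ""
            rows.append((f"a{i}", s, d, 1980, ""))
    return Pedigree.from_records(rows)


@pytest.fixture
def trio_pedigree():
    return Pedigree.from_records(
        [("s", "", "", 1970, "X"), ("d", "", "", 1970, "X"),
         ("o", "s", "d", 1975, "X")]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
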