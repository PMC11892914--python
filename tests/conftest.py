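import numpy as np
import pandas as pd
import pytest

from gutbrain.otu_processing import OtuTable


@pytest.fixture
def small_otu() -> OtuTable:
    """Six taxa x four samples with known totals and phyla."""
    counts = pd.DataFrame(
        {
            "c1": [5, 6, 100, 40, 3, 0],
            "c2": [3, 5, 80, 60, 2, 0],
            "d1": [2, 0, 10, 90, 5, 0],
            "d2": [0, 0, 15, 70, 6, 0],
        },
        index=[f"sp{i}" for i in range(1, 7)],
    )
    taxonomy = pd.Series([f"Species {i}" for i in range(1, 7)], index=counts.index)
    phylum = pd.Series(
        ["Firmicutes", "Firmicutes", "Bacteroidetes", "Firmicutes",
         "Bacteroidetes", "Actinobacteria"],
        index=counts.index,
    )
    groups = pd.Series(
        {"c1": "control", "c2": "control", "d1": "dementia", "d2": "dementia"}
    )
    return OtuTable(counts, taxonomy, phylum, groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
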