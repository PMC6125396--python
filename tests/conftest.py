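import numpy as np
import pandas as pd
import pytest

from phylosym.otu import OtuTable


def make_table(counts: dict, taxonomy: dict | None = None, species=None) -> OtuTable:
    """Build a small OtuTable from {sample: {otu: count}}."""
    counts_df = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    if taxonomy is None:
        taxonomy = {o: "k__Bacteria;p__P1" for o in counts_df.columns}
    if species is None:
        species = {s: s.split("_")[0] for s in counts_df.index}
    meta = pd.DataFrame(
        {
            "host_species": [species[s] for s in counts_df.index],
            "genus": [f"genus_{species[s]}" for s in counts_df.index],
            "tribe": ["tribe1"] * len(counts_df),
            "replicate": [s.split("_")[-1] for s in counts_df.index],
        },
        index=counts_df.index,
    )
    return OtuTable(
        counts=counts_df, taxonomy=pd.Series(taxonomy), metadata=meta
    )


@pytest.fixture
def three_sample_table() -> OtuTable:
    return make_table(
        {
            "spA_r1": {"o1": 5, "o2": 3, "o3": 0, "o4": 2},
            "spA_r2": {"o1": 4, "o2": 0, "o3": 1, "o4": 5},
            "spB_r1": {"o1": 0, "o2": 7, "o3": 2, "o4": 1},
        },
        taxonomy={
            "o1": "k__Bacteria;p__Firmicutes;c__Clostridia",
            "o2": "k__Bacteria;p__Firmicutes;c__Bacilli",
            "o3": "k__Bacteria;p__Bacteroidetes",
            "o4": "k__Bacteria",
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
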