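import numpy as np
import pandas as pd
import pytest

from histoptm.io import COLUMNS
from histoptm.simulate import GroupDesign, NoiseModel, generate_dataset, profile_from_marginals


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """Hand-written 4-row table: two forms x two replicates of one region."""
    rows = [
        ("7ds", 1, "H3.1K27-R40", "K27:me1", 80.0),
        ("7ds", 1, "H3.1K27-R40", "", 20.0),
        ("7ds", 2, "H3.1K27-R40", "K27:me1", 60.0),
        ("7ds", 2, "H3.1K27-R40", "", 40.0),
    ]
    return pd.DataFrame.from_records(rows, columns=COLUMNS)


@pytest.fixture
def two_group_designs() -> list[GroupDesign]:
    """Two small groups covering all regions, with distinct K27 profiles."""
    def margs(me1):
        return {
            "H3.1K27-R40": {"K27": {"me1": me1, "me2": 0.2}, "K36": {"me1": 0.2}},
            "H3.3K27-R40": {"K27": {"me1": 0.1, "me2": 0.1}, "K36": {"me1": 0.25}},
            "H3K9-R17": {"K9": {"me1": 0.2, "ac": 0.1}, "K14": {"ac": 0.1}},
            "H3K18-R26": {"K18": {"ac": 0.1}, "K23": {"ac": 0.15}},
            "H4G4-R17": {"K5": {"ac": 0.1}, "K8": {"ac": 0.1},
                         "K12": {"ac": 0.1}, "K16": {"ac": 0.2}},
        }

    designs = []
    for label, p31, me1 in (("groupA", 0.75, 0.3), ("groupB", 0.6, 0.15)):
        profiles = {
            rid: profile_from_marginals(rid, m) for rid, m in margs(me1).items()
        }
        designs.append(
            GroupDesign(label=label, variant_p31=p31, profiles=profiles,
                        n_replicates=4)
        )
    return designs


@pytest.fixture
def synthetic_records(two_group_designs) -> pd.DataFrame:
    return generate_dataset(two_group_designs, NoiseModel(sigma=0.2, seed=11))
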