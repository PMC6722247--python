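import numpy as np
import pandas as pd
import pytest

from metaborf import MetaboliteTable, SyntheticConfig, generate_table


def make_table(abundances, groups, subject_ids=None, metabolite_ids=None):
    """Hand-rolled MetaboliteTable from a plain subjects x metabolites array."""
    ab = np.asarray(abundances, dtype=float)
    n, p = ab.shape
    sids = subject_ids or [f"S{i+1}" for i in range(n)]
    mids = metabolite_ids or [f"M{j+1}" for j in range(p)]
    abundances = pd.DataFrame(ab, index=pd.Index(sids, name="subject_id"),
                              columns=pd.Index(mids, name="metabolite_id"))
    annotations = pd.DataFrame(
        {"mass": 100.0 + np.arange(p), "retention_index": 1000.0 + np.arange(p),
         "platform": "GC/MS"},
        index=abundances.columns,
    )
    labels = pd.Series(list(groups), index=abundances.index, name="group")
    return MetaboliteTable(abundances, labels, annotations)


@pytest.fixture
def toy_table():
    """4 subjects x 3 metabolites with one missing cell."""
    ab = [
        [10.0, 1.0, 5.0],
        [np.nan, 2.0, 6.0],
        [12.0, 3.0, 7.0],
        [11.0, 4.0, 8.0],
    ]
    return make_table(ab, ["resistant", "resistant", "control", "control"])


@pytest.fixture(scope="session")
def planted_table():
    """A 30-subject cohort with 5 strong discriminative metabolites among 120."""
    cfg = SyntheticConfig(n_metabolites=120, n_informative=5, log2_fold_change=2.0,
                          n_blocks=4, block_size=10, block_rho=0.7,
                          missing_quantile=0.10, seed=42)
    return generate_table(cfg)
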