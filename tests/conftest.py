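import warnings

import numpy as np
import pandas as pd
import pytest

import hscycle as h

warnings.filterwarnings("ignore", message=".*Identity link.*")


@pytest.fixture(scope="session")
def default_sim():
    """One default two-group experiment shared by read-only tests."""
    cfg = h.default_config(seed=11)
    return h.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def normalized_default(default_sim):
    m, meta, truth, sets = default_sim
    sf = h.compute_size_factors(m)
    norm = h.normalize(m, sf)
    return m, meta, truth, sets, sf, norm


@pytest.fixture
def tiny_matrix():
    """3 biological genes + 1 spike-in, 2 cells."""
    return h.CountMatrix(
        counts=np.array([[2, 4], [2, 4], [8, 16], [100, 100]]),
        gene_ids=np.array(["g1", "g2", "g3", "ERCC-00001"]),
        cell_ids=np.array(["c1", "c2"]),
        is_spikein=np.array([False, False, False, True]),
        is_mito=np.array([False, False, False, False]),
    )


def make_metadata(cell_ids, group="WT", **cols):
    df = pd.DataFrame({"cell_id": list(cell_ids)})
    df["group"] = group
    for k, v in cols.items():
        df[k] = v
    return h.CellMetadata(table=df)
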