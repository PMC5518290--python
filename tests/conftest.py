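import numpy as np
import pandas as pd
import pytest

from crtmiss.datamodel import TrialDataset


def make_dataset(arm, cluster, individual, x, y, k, m):
    """Build a TrialDataset directly from parallel value lists."""
    df = pd.DataFrame({
        "arm": np.asarray(arm, dtype=np.int64),
        "cluster": np.asarray(cluster, dtype=np.int64),
        "individual": np.asarray(individual, dtype=np.int64),
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
    })
    df["r"] = (~df["y"].isna()).astype(np.int64)
    return TrialDataset(df, k=k, m=m)


@pytest.fixture
def tiny_complete():
    """1 cluster per arm, 2 individuals, no missingness."""
    return make_dataset(
        arm=[0, 0, 1, 1], cluster=[1, 1, 1, 1], individual=[1, 2, 1, 2],
        x=[0.1, -0.4, 0.7, 1.2], y=[1, 0, 1, 1], k=1, m=2)


@pytest.fixture
def s1_small():
    """One complete S1 trial, 8 clusters of 20 per arm."""
    from crtmiss import dgm

    cfg, _ = dgm.scenario_preset("S1", k=8, m=20)
    return dgm.simulate_full_data(cfg, 20240917)


@pytest.fixture
def s1_small_incomplete(s1_small):
    from crtmiss import dgm

    _, mcfg = dgm.scenario_preset("S1", k=8, m=20)
    return dgm.impose_cdm_missingness(s1_small, mcfg, 61)
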