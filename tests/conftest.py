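import numpy as np
import pandas as pd
import pytest

import mirc


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated cohort shared across read-only tests."""
    cfg = mirc.default_config(
        n_patients_discovery=10,
        n_patients_validation=0,
        n_controls=8,
        n_mirna=60,
        n_other_ncrna={"snoRNA": 15, "tRNA": 15, "scRNA": 8, "other": 8},
        seed=20,
    )
    counts, meta = mirc.simulate_cohort(cfg)
    return cfg, counts, meta


@pytest.fixture()
def toy_counts():
    """2 features x 2 samples with one calibrator feature."""
    df = pd.DataFrame(
        {"s1": [1, 3, 10], "s2": [3, 1, 20]},
        index=["fA", "fB", "cal-01"],
    )
    return mirc.CountMatrix(
        df,
        {"fA": "miRNA", "fB": "tRNA", "cal-01": "other"},
        {"fA": False, "fB": False, "cal-01": True},
    )


def make_de(rows):
    """Build a DE table from (feature_id, logFC, adj_p) triples."""
    return pd.DataFrame(
        [
            {
                "feature_id": f,
                "logFC": lfc,
                "aveExpr": 5.0,
                "t": np.sign(lfc) * 3.0,
                "p": adj / 2,
                "adj_p": adj,
            }
            for f, lfc, adj in rows
        ],
        columns=["feature_id", "logFC", "aveExpr", "t", "p", "adj_p"],
    )
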