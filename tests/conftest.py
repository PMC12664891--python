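import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import redoxtmt as rt
from redoxtmt import mq_tables as mq

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded experiment reused across read-only tests."""
    params = rt.SimParams(rng_seed=11, n_proteins=40)
    tables, truth, design = rt.simulate_experiment(params)
    return {"params": params, "tables": tables, "truth": truth, "design": design}


@pytest.fixture(scope="session")
def small_fit(small_sim):
    model = rt.RedoxStoichiometryModel.from_tables(
        small_sim["tables"], small_sim["design"]
    )
    return model.fit()


@pytest.fixture
def two_channel_design():
    return rt.simple_design(["a", "b"], 1, carrier=False)


def _reporter_cols(n, family=mq.RAW_FAMILY):
    return [f"{family} {i + 1}" for i in range(n)]


@pytest.fixture
def mod_peptide_fixture(tmp_path):
    """Hand-written 3-row modificationSpecificPeptides.txt."""
    cols = (
        ["id", "Sequence", "Modifications", "Peptide ID", "Reverse",
         "Potential contaminant"] + _reporter_cols(10)
    )
    rows = [
        [0, "ACDEFK", mq.LIGHT_MOD, 0, "", ""] + [100.0 * (i + 1) for i in range(10)],
        [1, "ACDEFK", mq.HEAVY_MOD, 0, "", ""] + [10.0] * 9 + [0.0],
        [2, "LMNPQR", "Unmodified", 1, "+", ""] + [5.0] * 10,
    ]
    path = tmp_path / "modificationSpecificPeptides.txt"
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def make_design(n_conditions=3, n_replicates=3, carrier=True, **kw):
    conds = [f"c{i + 1}" for i in range(n_conditions)]
    return rt.simple_design(conds, n_replicates, carrier=carrier, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
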