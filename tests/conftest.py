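import numpy as np
import pandas as pd
import pytest

import gwasmunge as gm


@pytest.fixture(scope="session")
def backend():
    """Medium synthetic catalogue with every variant class represented."""
    return gm.make_synthetic_reference(
        42, n_variants=3000, nonbiallelic_frac=0.05, ambiguous_frac=0.15,
        position_collisions=8,
    )


@pytest.fixture(scope="session")
def small_backend():
    return gm.make_synthetic_reference(7, n_variants=500)


@pytest.fixture()
def clean_table(backend):
    """A 20-row table that has been through the pipeline (canonical, typed)."""
    raw, _ = gm.make_sumstats_fixture(backend, seed=5, n_rows=20)
    table, _ = gm.run_pipeline(raw, gm.QCConfig(), backend)
    return table


def frame(**cols) -> pd.DataFrame:
    """Shorthand: build an object-dtype DataFrame from column lists."""
    return pd.DataFrame({k: pd.Series(v, dtype=object) for k, v in cols.items()})


@pytest.fixture()
def make_frame():
    return frame
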