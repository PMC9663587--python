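import numpy as np
import pandas as pd
import pytest

from dyedrop.synthetic import IntensityModel, simulate_cell_table

NINE_DOSES = 10.0 ** np.arange(-4.0, 0.5, 0.5)  # nine-point half-log series, uM


@pytest.fixture(scope="session")
def nine_doses():
    return NINE_DOSES.copy()


@pytest.fixture(scope="session")
def mixed_well():
    """A 2000-cell well with all classes present (well-separated mixtures)."""
    counts = {"G1": 800, "S": 500, "G2": 300, "M": 100, "dead": 200, "corpse": 100}
    return simulate_cell_table(counts, IntensityModel(), seed=20260)


@pytest.fixture(scope="session")
def feature_csv(tmp_path_factory, mixed_well):
    path = tmp_path_factory.mktemp("io") / "cells.csv"
    mixed_well.cells.drop(columns=["true_class"]).to_csv(path, index=False)
    return path
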