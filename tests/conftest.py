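import io

import numpy as np
import pytest

from fsopa.table import ColumnRoleConfig, build_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(columns: dict, config: ColumnRoleConfig | None = None):
    """Build a FeatureTable from a column-name -> values mapping."""
    header = list(columns)
    rows = list(zip(*(columns[h] for h in header)))
    return build_table(header, rows, config)


@pytest.fixture
def tiny_csv():
    return io.StringIO("a,b\n1,x\n2,y\n3,z\n")


@pytest.fixture
def survival_table(rng):
    """Small table with a known single-covariate proportional-hazards outcome."""
    n = 300
    x = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    hazard = 0.1 * np.exp(0.8 * x)
    t = rng.exponential(1.0 / hazard)
    cens = rng.exponential(1.0 / (0.25 * 0.1))
    duration = np.minimum(t, cens)
    event = (t <= cens).astype(int)
    table = make_table(
        {"x": np.round(x, 4), "noise": np.round(noise, 4),
         "T": np.round(duration, 4), "E": event},
        ColumnRoleConfig(criterion="T", duration="T", event="E"))
    return table
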