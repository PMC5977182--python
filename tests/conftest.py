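import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import xsuppress as xs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_table(x_values, a_values, tissue="testis", sex="male"):
    """TissueTable straight from value lists, bypassing file I/O."""
    data = pd.DataFrame(
        {
            "gene_id": [f"x{i}" for i in range(len(x_values))]
            + [f"a{i}" for i in range(len(a_values))],
            "chromosome_class": ["X"] * len(x_values) + ["A"] * len(a_values),
            "mean_fpkm": list(x_values) + list(a_values),
        }
    )
    return xs.TissueTable(
        tissue=tissue,
        sex=sex,
        data=data,
        min_fpkm=0.0,
        max_fpkm=None,
        excluded={"unclassified": 0, "below_min": 0, "above_max": 0},
    )


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def small_records():
    """Five genes across X and autosomes in one tissue/sex."""
    mk = xs.GeneExpressionRecord
    return [
        mk("g1", "X", "testis", "male", (2.0, 4.0, 6.0)),
        mk("g2", "X", "testis", "male", (10.0, 12.0, 14.0)),
        mk("g3", "2L", "testis", "male", (8.0, 8.0, 8.0)),
        mk("g4", "3R", "testis", "male", (20.0, 22.0, 24.0)),
        mk("g5", "4", "testis", "male", (1.5, 1.5, 1.5)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20180504)
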