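import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_read_table():
    """Two samples, three replicates each, three species."""
    rows = []
    depths = {
        ("s1", "r1"): [40_000, 2_000, 100],
        ("s1", "r2"): [38_000, 1_500, 0],
        ("s1", "r3"): [41_000, 0, 80],
        ("s2", "r1"): [35_000, 900, 50],
        ("s2", "r2"): [36_000, 1_100, 60],
        ("s2", "r3"): [34_000, 1_000, 0],
    }
    for (s, r), counts in depths.items():
        for sp, c in zip(["spA", "spB", "spC"], counts):
            rows.append({"sample_id": s, "replicate_id": r,
                         "species_id": sp, "reads": c})
    return pd.DataFrame(rows)
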