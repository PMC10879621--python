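import numpy as np
import pandas as pd
import pytest

from mrmediation.estimators import make_table
from mrmediation.sumstats import COLUMNS


def sumstats_frame(rows):
    """Build a canonical summary-statistics table from dict rows."""
    defaults = {"chrom": "1", "pos": 1000, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.01,
                "pval": 1e-8, "n": 10000.0}
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d["snp_id"] = f"rs{i + 1}"
        d["pos"] = 1000 + i * 100_000
        d.update(r)
        full.append(d)
    return pd.DataFrame(full, columns=COLUMNS)


@pytest.fixture
def equal_se_table():
    """Ratios 0.5/1.0/1.5 with equal first-order SE 0.5 (beta_exp = 1)."""
    return make_table([1.0, 1.0, 1.0], [0.1] * 3, [0.5, 1.0, 1.5], [0.5] * 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240207)


def random_mr_table(rng, j=20, theta=0.5):
    bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.03, j)
    sy = rng.uniform(0.005, 0.05, j)
    by = rng.normal(theta * bx, sy)
    return make_table(bx, sx, by, sy)
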