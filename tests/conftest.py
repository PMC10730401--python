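import numpy as np
import pandas as pd
import pytest

from mitopath import enrichment as enr


@pytest.fixture
def small_de_table() -> pd.DataFrame:
    """Ten genes with distinct descending log2fc (g0 highest)."""
    return pd.DataFrame(
        {"gene": [f"g{i}" for i in range(10)], "log2fc": np.arange(10.0, 0.0, -1.0)}
    )


@pytest.fixture
def ranked10(small_de_table) -> enr.RankedGeneList:
    return enr.rank_genes(small_de_table)


def brute_force_bh(pvals):
    """Independent step-up oracle: q_(i) = min over tail of p_(j) * m / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        tail = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(tail))
    return q
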