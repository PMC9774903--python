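import warnings

import numpy as np
import pandas as pd
import pytest

import tissuexpr as tx


@pytest.fixture
def toy_matrix() -> tx.ExpressionMatrix:
    """4 genes × 6 samples over 3 tissues, hand-checkable values."""
    values = pd.DataFrame(
        {
            "A_r1": [10.0, 0.2, 0.0, 5.0],
            "A_r2": [12.0, 0.4, 0.0, 6.0],
            "B_r1": [9.0, 5.0, 0.0, 0.5],
            "B_r2": [11.0, 6.0, 0.0, 0.4],
            "C_r1": [10.5, 0.0, 0.0, 30.0],
            "C_r2": [9.5, 0.0, 2.0, 40.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    design = pd.Series(
        {"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B",
         "C_r1": "C", "C_r2": "C"}
    )
    return tx.ExpressionMatrix(values, design)


@pytest.fixture(scope="session")
def synth_default() -> tuple[tx.ExpressionMatrix, pd.DataFrame]:
    """The default planted atlas, seed 1 (shared across the suite)."""
    return tx.generate(tx.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def synth_summary(synth_default) -> tx.TissueSummary:
    matrix, _ = synth_default
    filtered = tx.filter_min_expressed_samples(matrix)
    return tx.summarize_by_tissue(filtered)


@pytest.fixture(scope="session")
def network_default(synth_default) -> tx.NetworkResult:
    """Full network stage on the default planted atlas (built once)."""
    matrix, _ = synth_default
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tx.build_network(matrix)


def brute_force_tsg(mean_table: pd.DataFrame, top_fraction=0.25,
                    sum_ratio=0.5, fold=3.0) -> dict[tuple[str, str], bool]:
    """Direct inequality evaluation of the three TSG criteria.

    Independent of the vectorized implementation: plain Python loops over
    every (gene, tissue) pair with a positive mean.
    """
    import math

    out = {}
    tissues = list(mean_table.columns)
    for t in tissues:
        col = mean_table[t]
        universe = [g for g in mean_table.index if col[g] > 0]
        k = max(1, math.ceil(top_fraction * len(universe))) if universe else 0
        ranked = sorted(universe, key=lambda g: -col[g])
        cutoff = col[ranked[k - 1]] if universe else None
        for g in universe:
            others = [mean_table.loc[g, u] for u in tissues if u != t]
            c1 = col[g] >= cutoff
            c2 = col[g] > sum_ratio * sum(others)
            c3 = col[g] > fold * max(others)
            out[(g, t)] = bool(c1 and c2 and c3)
    return out
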