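"""Tissue-specific gene (TSG) detection.

A gene is called specific to tissue *t* when all three criteria hold on
per-tissue average expression:

1. its mean in *t* ranks in the top 25% of genes expressed in *t*;
2. its mean in *t* exceeds 50% of the sum of its means in all other tissues;
3. its mean in *t* exceeds 3× its mean in every other tissue.

All inequalities are strict. A TSG additionally below the activity
threshold (mean FPKM < 1) in every non-target tissue is a "particular"
TSG — expressed in a single tissue only.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .profile import TissueSummary

__all__ = [
    "detect_tsg",
    "detect_particular_tsg",
    "tsg_counts_by_tissue",
    "top_particular_tsg",
]


def detect_tsg(
    summary: TissueSummary,
    top_fraction: float = 0.25,
    sum_ratio: float = 0.5,
    fold: float = 3.0,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Evaluate the three specificity criteria for every (gene, tissue).

    The top-fraction universe for each tissue is the set of genes with a
    positive mean there; ties at the rank boundary are all included. Rows
    are emitted only for (gene, tissue) pairs with a positive mean, so a
    gene that is zero everywhere yields no row.

    Returns a table with one row per candidate pair and columns for each
    criterion, the conjunction ``is_tsg``, and the quantities entering the
    inequalities.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if summary.mean.shape[1] < 2:
        raise ValueError("TSG detection needs at least 2 tissues")
    W = getattr(summary, statistic)
    tissues = list(W.columns)
    A = W.to_numpy(dtype=float)
    total = A.sum(axis=1)

    rows = []
    for j, tissue in enumerate(tissues):
        col = A[:, j]
        pos = col > 0
        n_pos = int(pos.sum())
        if n_pos == 0:
            continue
        k = max(1, math.ceil(top_fraction * n_pos))
        # value at rank k (descending) among positive means; ties included
        cutoff = np.sort(col[pos])[::-1][k - 1]
        crit_top = pos & (col >= cutoff)
        others = np.delete(A, j, axis=1)
        sum_other = total - col
        max_other = others.max(axis=1)
        crit_sum = col > sum_ratio * sum_other
        crit_fold = col > fold * max_other
        is_tsg = crit_top & crit_sum & crit_fold
        idx = np.nonzero(pos)[0]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": W.index[idx],
                    "tissue": tissue,
                    "target_mean": col[idx],
                    "max_other_mean": max_other[idx],
                    "sum_other_means": sum_other[idx],
                    "crit_top25": crit_top[idx],
                    "crit_sum": crit_sum[idx],
                    "crit_fold": crit_fold[idx],
                    "is_tsg": is_tsg[idx],
                }
            )
        )
    if not rows:
        table = pd.DataFrame(
            columns=["gene_id", "tissue", "target_mean", "max_other_mean",
                     "sum_other_means", "crit_top25", "crit_sum", "crit_fold",
                     "is_tsg"]
        )
    else:
        table = pd.concat(rows, ignore_index=True)
    table["is_particular"] = False
    return table


def detect_particular_tsg(
    tsg_table: pd.DataFrame,
    summary: TissueSummary,
    silence_threshold: float = 1.0,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Flag TSGs expressed in their target tissue only.

    A TSG is particular when its per-tissue mean is below
    ``silence_threshold`` (strict) in every non-target tissue and at least
    the threshold in the target tissue — the FPKM < 1 inactivity rule
    applied to tissue means.
    """
    W = getattr(summary, statistic)
    table = tsg_table.copy()
    table["is_particular"] = False
    hits = table.index[table["is_tsg"]]
    for i in hits:
        gene = table.at[i, "gene_id"]
        tissue = table.at[i, "tissue"]
        means = W.loc[gene]
        others = means.drop(tissue)
        table.at[i, "is_particular"] = bool(
            (others < silence_threshold).all() and means[tissue] >= silence_threshold
        )
    return table


def tsg_counts_by_tissue(tsg_table: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue counts of TSG and particular-TSG calls."""
    if tsg_table.empty:
        return pd.DataFrame(columns=["tissue", "n_tsg", "n_particular"])
    counts = (
        tsg_table.groupby("tissue", sort=False)[["is_tsg", "is_particular"]]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"is_tsg": "n_tsg", "is_particular": "n_particular"})
    )
    return counts


def top_particular_tsg(tsg_table: pd.DataFrame, n: int = 19) -> pd.DataFrame:
    """The ``n`` most highly expressed particular TSGs (by target mean)."""
    part = tsg_table[tsg_table["is_particular"]]
    return part.sort_values(
        ["target_mean", "gene_id"], ascending=[False, True]
    ).head(n).reset_index(drop=True)
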