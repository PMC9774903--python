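"""Hypergeometric over-representation analysis (ORA).

Tests whether a query gene list overlaps a gene set more than expected
under uniform sampling from a background universe: the p-value is the
upper tail P(X >= overlap) of the hypergeometric distribution with the
universe as population, the set as successes and the query size as draws.
Benjamini–Hochberg FDR is applied across the tested sets.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

__all__ = ["hypergeom_pvalue", "hypergeometric_ora", "enrich_gene_groups"]


def hypergeom_pvalue(overlap: int, universe_size: int, set_size: int,
                     query_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap)."""
    if not (0 <= set_size <= universe_size and 0 <= query_size <= universe_size):
        raise ValueError("set and query sizes must lie within the universe")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))
    return min(max(p, 0.0), 1.0)


def hypergeometric_ora(
    query: Iterable[str],
    sets: Iterable[GeneSet],
    universe: Iterable[str],
    min_set_size: int = 5,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Test a query gene list against each gene set.

    Gene sets are intersected with the universe before testing; sets
    smaller than ``min_set_size`` after intersection, or overlapping the
    query by fewer than ``min_overlap`` genes, are not reported. Rows are
    ordered by p then set_id for determinism.
    """
    from statsmodels.stats.multitest import multipletests

    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    stray = query - universe
    if stray:
        raise ValueError(
            f"{len(stray)} query genes outside the universe (e.g. {sorted(stray)[:3]})"
        )
    rows = []
    for gs in sets:
        members = gs.members & universe
        if len(members) < min_set_size:
            continue
        k = len(members & query)
        if k < min_overlap:
            continue
        p = hypergeom_pvalue(k, len(universe), len(members), len(query))
        rows.append(
            {
                "set_id": gs.set_id,
                "description": gs.description,
                "overlap": k,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["set_id", "description", "overlap", "set_size", "query_size",
                 "universe_size", "p"],
    )
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "set_id"]).reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table


def enrich_gene_groups(
    groups: Mapping[str, Iterable[str]],
    sets: Iterable[GeneSet],
    universe: Iterable[str],
    min_set_size: int = 5,
    min_overlap: int = 1,
) -> dict[str, pd.DataFrame]:
    """Run ORA for several named gene lists against the same collection.

    Group genes outside the universe are dropped; a group left disjoint
    from the universe yields an empty table with a warning.
    """
    sets = list(sets)
    universe = set(universe)
    out: dict[str, pd.DataFrame] = {}
    for name, genes in groups.items():
        inside = set(genes) & universe
        if not inside:
            warnings.warn(f"group {name!r} is disjoint from the universe")
            out[name] = pd.DataFrame(
                columns=["set_id", "description", "overlap", "set_size",
                         "query_size", "universe_size", "p", "fdr"]
            )
            continue
        out[name] = hypergeometric_ora(
            inside, sets, universe, min_set_size=min_set_size,
            min_overlap=min_overlap,
        )
    return out
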