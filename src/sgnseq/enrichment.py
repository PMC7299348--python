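"""Hypergeometric over-representation of gene groups in classified lists.

For a query of n genes drawn from a universe of N, a group covering K
universe genes, and an overlap of k, the enrichment p-value is the upper
tail P[X >= k] with X ~ Hypergeometric(N, K, n) — the chance of at least
as large an overlap under sampling without replacement. BH-adjusted
p-values across the groups of a collection are reported alongside the raw
ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import adjust_bh

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to an analysis universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("enrichment universe must be non-empty")
        self.sets = {name: s & self.universe for name, s in self.sets.items()}

    @classmethod
    def from_gmt_sets(cls, sets: dict[str, set[str]], universe) -> "GeneSetCollection":
        return cls(dict(sets), set(universe))


def hypergeom_enrichment(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every group against one query.

    Query genes outside the universe are dropped (logged). Columns:
    group, k, K, n, N, p_raw, p_adj (BH across the collection's groups).
    """
    query = set(query)
    inside = query & collection.universe
    dropped = len(query) - len(inside)
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", dropped)
    n = len(inside)
    N = len(collection.universe)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(inside & members)
        # P[X >= k]; sf(k-1) is the exact upper tail
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["group", "k", "K", "n", "N", "p_raw"])
    out["p_adj"] = adjust_bh(out["p_raw"].to_numpy()) if len(out) else []
    return out.sort_values("p_raw", ignore_index=True)


def enrich_all_categories(
    categories: dict[str, list[str]],
    collections: dict[str, GeneSetCollection],
) -> dict[tuple[str, str], pd.DataFrame]:
    """Enrichment scan of every pattern category against every annotation.

    Returns ``(category, annotation) -> record table``; empty categories
    yield empty tables.
    """
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for cat, genes in categories.items():
        for ann_name, coll in collections.items():
            if not genes:
                results[(cat, ann_name)] = pd.DataFrame(
                    columns=["group", "k", "K", "n", "N", "p_raw", "p_adj"]
                )
            else:
                results[(cat, ann_name)] = hypergeom_enrichment(genes, coll)
    return results
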