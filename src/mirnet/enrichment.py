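"""Hypergeometric over-representation analysis against GMT gene sets.

Replaces a web enrichment service with an explicit statistic: for a query
list of n genes drawn from a universe of M genes, a term with K members
and an overlap of k has upper-tail probability P(X >= k) under the
hypergeometric null.  p-values are Benjamini-Hochberg adjusted across all
terms tested in a run; the conventional significance cut-off is adjusted
p < 0.05.  The universe should be the set of genes actually tested for
differential expression, not the whole genome.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["read_gmt", "write_gmt", "hypergeom_pvalue", "ora_analysis"]


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT file: term_id TAB description TAB gene1 TAB gene2 ..."""
    collection: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term_id, description, *genes = fields
        members = sorted(set(g for g in genes if g))
        if not members:
            raise ValueError(f"term {term_id} has no members")
        collection[term_id] = {"description": description, "genes": members}
    return collection


def write_gmt(collection: dict[str, dict], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([term, meta["description"], *meta["genes"]])
        for term, meta in collection.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def hypergeom_pvalue(k: int, K: int, n: int, M: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(M, K, n)."""
    if K > M or n > M or min(k, K, n, M) < 0:
        raise ValueError("need K <= M and n <= M with non-negative arguments")
    if not (max(0, K + n - M) <= k <= min(K, n)):
        raise ValueError("overlap k impossible for these (K, n, M)")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def ora_analysis(
    query_genes,
    collection: dict[str, dict],
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a gene list against every term in a collection.

    Genes outside the universe are dropped (with a warning); term members
    are likewise intersected with the universe.  One row per term with at
    least one overlapping gene; BH correction runs across *all* tested
    terms.  Rows sorted by (p_adj, p_raw, term_id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe were dropped",
                       len(outside))
    query &= universe
    m_total = len(universe)
    n_query = len(query)

    rows = []
    for term_id in sorted(collection):
        members = set(collection[term_id]["genes"]) & universe
        if not members:
            continue
        overlap = sorted(query & members)
        p = hypergeom_pvalue(len(overlap), len(members), n_query, m_total)
        rows.append(
            {
                "term_id": term_id,
                "term_name": collection[term_id]["description"],
                "k": len(overlap),
                "n": n_query,
                "K": len(members),
                "M": m_total,
                "p_raw": p,
                "fold_enrichment": (
                    (len(overlap) / n_query) / (len(members) / m_total)
                    if n_query else 0.0
                ),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not query:
        logger.warning("empty query after universe intersection")
    table = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "n", "K", "M", "p_raw",
                 "fold_enrichment", "overlap_genes"],
    )
    if table.empty:
        table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        return table
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    table = table[table["k"] >= 1]
    return table.sort_values(
        ["p_adj", "p_raw", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
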