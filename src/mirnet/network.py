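"""Anti-correlation-filtered miRNA-mRNA regulatory network construction.

Predicted miRNA->gene interactions are filtered on binding region and
binding probability (> 0.95), intersected with the differential-expression
calls, scored with Spearman's rank correlation across the samples shared
by the two expression platforms, and retained when the correlation is
strictly below -0.5 (miRNAs repress their targets, so a regulator and its
target should move in opposite directions).  The retained bipartite graph
is split into an up-miRNA/down-gene and a down-miRNA/up-gene subnetwork
and can be exported as SIF, GraphML or an edge-list TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionPair",
    "filter_predictions",
    "candidate_pairs",
    "spearman_rho",
    "score_pairs",
    "build_network",
    "export_network",
    "read_network",
]

PREDICTION_COLUMNS = [
    "mirna_id",
    "gene_id",
    "region",
    "binding_probability",
    "validated",
]


@dataclass(frozen=True)
class InteractionPair:
    """A scored candidate miRNA->gene interaction."""

    mirna_id: str
    gene_id: str
    rho: float
    n_samples: int
    mirna_direction: str
    gene_direction: str
    binding_probability: float
    validated: bool


def filter_predictions(
    predictions: pd.DataFrame,
    min_probability: float = 0.95,
    required_region: str = "3UTR",
) -> pd.DataFrame:
    """Keep confident binding-site predictions in the required region.

    Probability must be strictly greater than ``min_probability``.
    Duplicate (miRNA, gene) rows collapse to one, keeping the maximum
    probability and OR-ing the validated flags.  Rows with a probability
    outside [0, 1] are dropped with a warning.
    """
    df = predictions.copy()
    bad = ~df["binding_probability"].between(0.0, 1.0)
    if bad.any():
        logger.warning("dropping %d rows with probability outside [0, 1]", bad.sum())
        df = df[~bad]
    df = df[(df["region"] == required_region)
            & (df["binding_probability"] > min_probability)]
    if df.empty:
        return df.reset_index(drop=True)
    df = (
        df.groupby(["mirna_id", "gene_id"], as_index=False, sort=False)
        .agg(
            region=("region", "first"),
            binding_probability=("binding_probability", "max"),
            validated=("validated", "any"),
        )
    )
    return df[PREDICTION_COLUMNS].reset_index(drop=True)


def candidate_pairs(
    filtered_predictions: pd.DataFrame,
    de_mirnas: tuple[list[str], list[str]],
    de_genes: tuple[list[str], list[str]],
    opposite_only: bool = True,
) -> pd.DataFrame:
    """Intersect predictions with the DE calls and annotate directions.

    ``de_mirnas`` / ``de_genes`` are (up, down) ID lists.  When
    ``opposite_only`` is set, only up-miRNA/down-gene and
    down-miRNA/up-gene pairs survive.
    """
    mirna_dir = {m: "up" for m in de_mirnas[0]} | {m: "down" for m in de_mirnas[1]}
    gene_dir = {g: "up" for g in de_genes[0]} | {g: "down" for g in de_genes[1]}
    df = filtered_predictions.copy()
    df["mirna_direction"] = df["mirna_id"].map(mirna_dir)
    df["gene_direction"] = df["gene_id"].map(gene_dir)
    df = df.dropna(subset=["mirna_direction", "gene_direction"])
    if opposite_only:
        df = df[df["mirna_direction"] != df["gene_direction"]]
    return df.reset_index(drop=True)


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation (average ranks for ties).

    Returns NaN when either vector is constant; callers drop such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def score_pairs(
    pairs: pd.DataFrame,
    gene_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    sample_sheet: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach Spearman rho (over shared samples) to each candidate pair.

    Correlation uses only the intersection of sample IDs present in both
    matrices (and in the sample sheet, if given); pairs whose expression
    is constant on those samples are dropped and counted in the log.
    """
    shared = [s for s in gene_expr.columns if s in set(mirna_expr.columns)]
    if sample_sheet is not None:
        keep = set(sample_sheet["sample_id"])
        shared = [s for s in shared if s in keep]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    records = []
    dropped = 0
    for row in pairs.itertuples(index=False):
        if row.gene_id not in gene_expr.index or row.mirna_id not in mirna_expr.index:
            dropped += 1
            continue
        rho = spearman_rho(
            mirna_expr.loc[row.mirna_id, shared].to_numpy(),
            gene_expr.loc[row.gene_id, shared].to_numpy(),
        )
        if math.isnan(rho):
            dropped += 1
            continue
        records.append(
            {
                "mirna_id": row.mirna_id,
                "gene_id": row.gene_id,
                "rho": rho,
                "n_samples": len(shared),
                "mirna_direction": row.mirna_direction,
                "gene_direction": row.gene_direction,
                "binding_probability": row.binding_probability,
                "validated": bool(row.validated),
            }
        )
    if dropped:
        logger.info("dropped %d pairs (missing feature or constant vector)", dropped)
    return pd.DataFrame(
        records,
        columns=[
            "mirna_id", "gene_id", "rho", "n_samples", "mirna_direction",
            "gene_direction", "binding_probability", "validated",
        ],
    )


def build_network(
    scored_pairs: pd.DataFrame,
    rho_threshold: float = -0.5,
    node_attrs: dict[str, dict] | None = None,
) -> dict[str, nx.DiGraph]:
    """Retain pairs with rho strictly below the threshold as a digraph.

    Returns ``{"full": G, "up_mirna_down_gene": G1, "down_mirna_up_gene":
    G2}``.  ``node_attrs`` optionally maps node ID -> attribute dict
    (log2FC, significance) merged onto the graph nodes.
    """
    kept = scored_pairs[scored_pairs["rho"] < rho_threshold]
    if kept.empty:
        logger.warning("no interaction passed rho < %s; network is empty",
                       rho_threshold)

    def make_graph(rows: pd.DataFrame) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in rows.itertuples(index=False):
            g.add_node(row.mirna_id, node_type="mirna",
                       direction=row.mirna_direction)
            g.add_node(row.gene_id, node_type="gene", direction=row.gene_direction)
            g.add_edge(
                row.mirna_id,
                row.gene_id,
                rho=float(row.rho),
                binding_probability=float(row.binding_probability),
                validated=bool(row.validated),
            )
        if node_attrs:
            for node in g.nodes:
                for key, value in node_attrs.get(node, {}).items():
                    g.nodes[node][key] = value
        return g

    up_down = kept[(kept["mirna_direction"] == "up")
                   & (kept["gene_direction"] == "down")]
    down_up = kept[(kept["mirna_direction"] == "down")
                   & (kept["gene_direction"] == "up")]
    return {
        "full": make_graph(kept),
        "up_mirna_down_gene": make_graph(up_down),
        "down_mirna_up_gene": make_graph(down_up),
    }


def network_summary(network: nx.DiGraph) -> dict[str, int]:
    mirnas = [n for n, d in network.nodes(data=True) if d.get("node_type") == "mirna"]
    genes = [n for n, d in network.nodes(data=True) if d.get("node_type") == "gene"]
    validated = sum(1 for _, _, d in network.edges(data=True) if d.get("validated"))
    return {
        "n_mirnas": len(mirnas),
        "n_genes": len(genes),
        "n_edges": network.number_of_edges(),
        "n_validated_edges": validated,
    }


def export_network(network: nx.DiGraph, fmt: str, path: str | Path) -> Path:
    """Write the network as SIF, GraphML or an edge-list TSV."""
    path = Path(path)
    if fmt == "sif":
        lines = [f"{u}\ttargets\t{v}" for u, v in network.edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "tsv":
        rows = [
            {
                "mirna_id": u,
                "gene_id": v,
                "rho": f"{d['rho']:.8g}",
                "binding_probability": f"{d['binding_probability']:.8g}",
                "validated": d["validated"],
            }
            for u, v, d in network.edges(data=True)
        ]
        pd.DataFrame(
            rows,
            columns=["mirna_id", "gene_id", "rho", "binding_probability", "validated"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    return path


def read_network(path: str | Path) -> nx.DiGraph:
    """Re-import a GraphML export."""
    return nx.read_graphml(path)
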