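"""Positional clustering of dysregulated genes, miRNAs and disease SNPs.

Dysregulated elements that co-localize on a chromosome may share regional
regulation (methylation, chromatin state) or mark a susceptibility locus.
A cluster is a maximal run of two or more elements in which consecutive
elements (sorted by start, with a running maximum end to absorb nested
intervals) overlap or lie at most 20 kbp apart.  Clusters of five or more
elements of any type are high-density regions; high-density regions made
up exclusively of SNPs are flagged excluded from the analysis.  The module
also assigns nearest genes to SNPs, normalizes element counts per
chromosome, and classifies co-expression of intronic/exonic miRNAs with
their host genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "HostCoexpressionRecord",
    "detect_clusters",
    "clusters_table",
    "nearest_genes",
    "chromosome_density",
    "host_gene_coexpression",
]

DEFAULT_MAX_GAP_BP = 20_000
DEFAULT_HIGH_DENSITY_MIN = 5


@dataclass
class Cluster:
    """A run of co-localized genomic elements on one chromosome."""

    chromosome: str
    start: int
    end: int
    member_ids: list[str]
    member_types: list[str]
    high_density: bool = False
    snp_only: bool = False
    excluded: bool = False

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class HostCoexpressionRecord:
    mirna_id: str
    host_gene_id: str
    context: str
    mirna_direction: str
    host_direction: str
    same_direction: bool
    both_significant: bool


def _check_elements(elements: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "start", "end", "element_id", "element_type"}
    missing = required - set(elements.columns)
    if missing:
        raise ValueError(f"element table missing columns: {sorted(missing)}")
    bad = elements["start"] >= elements["end"]
    if (elements["start"] < 0).any() or bad.any():
        raise ValueError("malformed intervals: need 0 <= start < end")
    return elements


def detect_clusters(
    elements: pd.DataFrame,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    high_density_min: int = DEFAULT_HIGH_DENSITY_MIN,
) -> list[Cluster]:
    """Single-linkage sweep clustering of elements along each chromosome.

    Elements are sorted by (start, end, element_id); an element joins the
    open cluster when its start is within ``max_gap_bp`` (inclusive) of the
    running maximum end.  Only runs of two or more elements are emitted;
    singletons are discarded.
    """
    elements = _check_elements(elements)
    clusters: list[Cluster] = []
    for chrom, group in elements.groupby("chrom", sort=True):
        rows = group.sort_values(
            ["start", "end", "element_id"], kind="mergesort"
        ).itertuples(index=False)
        open_members: list = []
        max_end = None
        for row in rows:
            if max_end is not None and row.start - max_end <= max_gap_bp:
                open_members.append(row)
                max_end = max(max_end, row.end)
            else:
                if len(open_members) >= 2:
                    clusters.append(_finalize(chrom, open_members, high_density_min))
                open_members = [row]
                max_end = row.end
        if len(open_members) >= 2:
            clusters.append(_finalize(chrom, open_members, high_density_min))
    return clusters


def _finalize(chrom: str, members: list, high_density_min: int) -> Cluster:
    types = [m.element_type for m in members]
    snp_only = all(t == "snp" for t in types)
    high = len(members) >= high_density_min
    return Cluster(
        chromosome=chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        member_ids=[m.element_id for m in members],
        member_types=types,
        high_density=high,
        snp_only=snp_only,
        excluded=high and snp_only,
    )


def clusters_table(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chromosome,
                "start": c.start,
                "end": c.end,
                "size": c.size,
                "member_ids": ",".join(c.member_ids),
                "member_types": ",".join(c.member_types),
                "high_density": c.high_density,
                "snp_only": c.snp_only,
                "excluded": c.excluded,
            }
            for c in clusters
        ],
        columns=["chrom", "start", "end", "size", "member_ids", "member_types",
                 "high_density", "snp_only", "excluded"],
    )


def _interval_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    """Gap between two half-open intervals; 0 when they overlap or touch."""
    if s1 < e2 and s2 < e1:
        return 0
    return s2 - e1 if s2 >= e1 else s1 - e2


def nearest_genes(
    snps: pd.DataFrame,
    gene_elements: pd.DataFrame,
    max_distance_bp: int | None = None,
) -> pd.DataFrame:
    """Assign each SNP the gene(s) at minimal genomic distance.

    A SNP inside a gene gets distance 0; ties return every gene at the
    minimum.  SNPs on gene-less chromosomes (or beyond ``max_distance_bp``)
    get an empty assignment, which is counted in the log.
    """
    _check_elements(snps)
    _check_elements(gene_elements)
    genes_by_chrom = {c: g for c, g in gene_elements.groupby("chrom")}
    rows = []
    unassigned = 0
    for snp in snps.itertuples(index=False):
        genes = genes_by_chrom.get(snp.chrom)
        assigned: list[str] = []
        best = None
        if genes is not None:
            dists = np.array(
                [
                    _interval_distance(snp.start, snp.end, g.start, g.end)
                    for g in genes.itertuples(index=False)
                ]
            )
            best = int(dists.min())
            if max_distance_bp is None or best <= max_distance_bp:
                ids = genes["element_id"].to_numpy()
                assigned = sorted(ids[dists == best])
            else:
                best = None
        if not assigned:
            unassigned += 1
        rows.append(
            {
                "snp_id": snp.element_id,
                "chrom": snp.chrom,
                "position": snp.start,
                "nearest_genes": ",".join(assigned),
                "distance_bp": best if assigned else pd.NA,
            }
        )
    if unassigned:
        logger.info("%d SNPs had no gene assignment", unassigned)
    return pd.DataFrame(rows)


def chromosome_density(
    elements: pd.DataFrame,
    chromosome_sizes: pd.DataFrame,
    genes_per_chromosome: dict[str, int] | pd.Series,
) -> pd.DataFrame:
    """Element counts per chromosome, normalized to size and gene content.

    Reports the raw count, count per Mbp, and count per annotated gene for
    every chromosome in ``chromosome_sizes``.
    """
    sizes = chromosome_sizes.set_index("chrom")["length_bp"]
    if (sizes <= 0).any():
        raise ValueError("chromosome sizes must be strictly positive")
    counts = elements.groupby("chrom").size()
    gene_counts = pd.Series(genes_per_chromosome)
    rows = []
    for chrom, size in sizes.items():
        n = int(counts.get(chrom, 0))
        n_genes = int(gene_counts.get(chrom, 0))
        rows.append(
            {
                "chrom": chrom,
                "n_elements": n,
                "per_mbp": n / (size / 1e6),
                "per_gene": n / n_genes if n_genes else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def host_gene_coexpression(
    mirna_annotations: pd.DataFrame,
    de_mirna_table: pd.DataFrame,
    de_gene_table: pd.DataFrame,
    *,
    fdr: float = 0.05,
    lfc: float = 1.0,
    mirna_p: float = 0.01,
) -> tuple[list[HostCoexpressionRecord], dict[str, int]]:
    """Co-expression of intronic/exonic DE miRNAs with their host genes.

    For every miRNA passing the miRNA significance rule whose annotation
    carries an intronic or exonic host gene present in the gene DE table:
    ``same_direction`` compares the signs of the two log2 fold changes and
    ``both_significant`` additionally requires the host to pass the gene
    rule.  Returns the records plus summary counts (n_hosted,
    n_same_direction, n_both_significant).
    """
    records: list[HostCoexpressionRecord] = []
    de_mirnas = de_mirna_table[de_mirna_table["p_raw"] < mirna_p]
    for row in mirna_annotations.itertuples(index=False):
        if row.context not in ("intronic", "exonic") or row.host_gene_id in (".", ""):
            continue
        if row.element_id not in de_mirnas.index:
            continue
        if row.host_gene_id not in de_gene_table.index:
            logger.info("host gene %s absent from gene table; skipped",
                        row.host_gene_id)
            continue
        m = de_mirnas.loc[row.element_id]
        h = de_gene_table.loc[row.host_gene_id]
        host_significant = bool(h["p_adj"] < fdr and abs(h["log2FC"]) > lfc)
        records.append(
            HostCoexpressionRecord(
                mirna_id=row.element_id,
                host_gene_id=row.host_gene_id,
                context=row.context,
                mirna_direction="up" if m["log2FC"] > 0 else "down",
                host_direction="up" if h["log2FC"] > 0 else "down",
                same_direction=bool(np.sign(m["log2FC"]) == np.sign(h["log2FC"])),
                both_significant=host_significant,
            )
        )
    summary = {
        "n_hosted": len(records),
        "n_same_direction": sum(r.same_direction for r in records),
        "n_both_significant": sum(r.both_significant for r in records),
    }
    return records, summary
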