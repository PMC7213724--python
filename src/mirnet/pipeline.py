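"""End-to-end orchestration: QC -> DE -> network -> enrichment -> loci.

One YAML configuration drives the whole analysis deterministically; every
output file is checksummed into a manifest so that identical inputs and
configuration yield an identical run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clusters as cl
from . import diffexpr as de
from . import enrichment as enr
from . import network as net

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for a full pipeline run."""

    counts: str
    mirna_intensity: str
    samples: str
    predictions: str
    genes_bed: str = ""
    mirnas_bed: str = ""
    snps_bed: str = ""
    chrom_sizes: str = ""
    gmt: str = ""
    out_dir: str = "mirnet_out"
    # thresholds (defaults are the conventional printed cut-offs)
    fdr: float = 0.05
    lfc: float = 1.0
    mirna_p: float = 0.01
    min_probability: float = 0.95
    required_region: str = "3UTR"
    rho_threshold: float = -0.5
    max_gap_bp: int = 20_000
    high_density_min: int = 5
    alpha: float = 0.05
    # flags
    opposite_only: bool = True
    exclude_qc_outliers: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fdr < 1 and 0 < self.mirna_p < 1 and 0 < self.alpha < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if not 0 <= self.min_probability <= 1:
            raise ValueError("min_probability must lie in [0, 1]")
        if not -1 <= self.rho_threshold <= 0:
            raise ValueError("rho_threshold must lie in [-1, 0]")
        if self.max_gap_bp < 0 or self.high_density_min < 2:
            raise ValueError("invalid clustering parameters")
        for name in ("counts", "mirna_intensity", "samples", "predictions"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")


@dataclass
class RunReport:
    manifest: dict[str, str] = field(default_factory=dict)  # file -> sha256
    counts: dict[str, int] = field(default_factory=dict)  # stage funnel
    log: list[str] = field(default_factory=list)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every analysis stage and write all result tables.

    Stage order: sample QC, gene DE, miRNA DE, prediction filtering, DE
    intersection, correlation scoring, network build and export, ORA of
    up/down DEGs and of network target genes, positional clustering with
    nearest-gene and density tables, host-gene co-expression.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    def note(msg: str) -> None:
        logger.info(msg)
        report.log.append(msg)

    def save(df: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        report.manifest[name] = _sha256(path)
        return path

    counts = _read_matrix(config.counts)
    mirna = _read_matrix(config.mirna_intensity)
    samples = pd.read_csv(config.samples, sep="\t")
    groups = samples.set_index("sample_id")["group"]
    note(f"loaded {counts.shape[0]} genes, {mirna.shape[0]} miRNAs, "
         f"{len(samples)} samples")

    # ---- QC ---------------------------------------------------------------
    lognorm_all = de.log_normalize(counts)
    qc_genes = de.sample_qc(lognorm_all)
    qc_mirna = de.sample_qc(mirna)
    outliers = sorted(set(qc_genes.outliers) | set(qc_mirna.outliers))
    note(f"QC outliers: {outliers or 'none'}")
    save(qc_genes.distance_matrix, "qc_gene_distances.tsv")
    save(qc_mirna.distance_matrix, "qc_mirna_distances.tsv")
    if config.exclude_qc_outliers and outliers:
        keep = [s for s in counts.columns if s not in outliers]
        counts = counts[keep]
        mirna = mirna[[s for s in mirna.columns if s not in outliers]]
        samples = samples[~samples["sample_id"].isin(outliers)]
        groups = groups.drop(index=outliers, errors="ignore")
        note(f"excluded QC outliers from all fits: {outliers}")

    # ---- differential expression ------------------------------------------
    expressed = counts.loc[(counts.sum(axis=1) > 0)]
    n_dropped = counts.shape[0] - expressed.shape[0]
    if n_dropped:
        note(f"dropped {n_dropped} all-zero genes before testing")
    lognorm = de.log_normalize(expressed)
    gene_table, _ = de.moderated_t_table(lognorm, groups)
    gene_table = de.annotate_directions(gene_table, "gene",
                                        fdr=config.fdr, lfc=config.lfc)
    mirna_table, _ = de.moderated_t_table(mirna, groups)
    mirna_table = de.annotate_directions(mirna_table, "mirna",
                                         mirna_p=config.mirna_p)
    save(gene_table, "de_genes.tsv")
    save(mirna_table, "de_mirnas.tsv")
    de_genes = de.select_de(gene_table, "gene", fdr=config.fdr, lfc=config.lfc)
    de_mirnas = de.select_de(mirna_table, "mirna", mirna_p=config.mirna_p)
    report.counts["n_de_genes"] = len(de_genes[0]) + len(de_genes[1])
    report.counts["n_de_mirnas"] = len(de_mirnas[0]) + len(de_mirnas[1])
    note(f"DE: {report.counts['n_de_genes']} genes "
         f"({len(de_genes[0])} up / {len(de_genes[1])} down), "
         f"{report.counts['n_de_mirnas']} miRNAs")

    # ---- network ----------------------------------------------------------
    predictions = pd.read_csv(config.predictions, sep="\t")
    report.counts["n_predictions"] = len(predictions)
    filtered = net.filter_predictions(predictions, config.min_probability,
                                      config.required_region)
    report.counts["n_predictions_confident"] = len(filtered)
    pairs = net.candidate_pairs(filtered, de_mirnas, de_genes,
                                opposite_only=config.opposite_only)
    report.counts["n_candidate_pairs"] = len(pairs)
    scored = net.score_pairs(pairs, lognorm, mirna, samples)
    save(scored, "scored_pairs.tsv", index=False)
    node_attrs = {
        **{g: {"log2FC": float(gene_table.loc[g, "log2FC"]),
               "p_adj": float(gene_table.loc[g, "p_adj"])}
           for g in gene_table.index},
        **{m: {"log2FC": float(mirna_table.loc[m, "log2FC"]),
               "p_raw": float(mirna_table.loc[m, "p_raw"])}
           for m in mirna_table.index},
    }
    networks = net.build_network(scored, config.rho_threshold, node_attrs)
    summary = net.network_summary(networks["full"])
    report.counts.update({f"network_{k}": v for k, v in summary.items()})
    note(f"network: {summary}")
    for name, graph in networks.items():
        net.export_network(graph, "graphml", out / f"network_{name}.graphml")
        net.export_network(graph, "sif", out / f"network_{name}.sif")
        net.export_network(graph, "tsv", out / f"network_{name}.tsv")
        for ext in ("graphml", "sif", "tsv"):
            fname = f"network_{name}.{ext}"
            report.manifest[fname] = _sha256(out / fname)

    # ---- enrichment --------------------------------------------------------
    if config.gmt:
        collection = enr.read_gmt(config.gmt)
        universe = list(gene_table.index)
        target_genes = sorted(
            {v for _, v, d in networks["full"].edges(data=True)}
        )
        queries = {
            "ora_up_degs.tsv": de_genes[0],
            "ora_down_degs.tsv": de_genes[1],
            "ora_network_targets.tsv": target_genes,
        }
        for name, query in queries.items():
            table = enr.ora_analysis(query, collection, universe, config.alpha)
            save(table, name, index=False)
        note("enrichment tables written")

    # ---- positional clustering --------------------------------------------
    if config.genes_bed and config.mirnas_bed and config.snps_bed:
        genes_bed = pd.read_csv(config.genes_bed, sep="\t", keep_default_na=False)
        mirnas_bed = pd.read_csv(config.mirnas_bed, sep="\t", keep_default_na=False)
        snps_bed = pd.read_csv(config.snps_bed, sep="\t", keep_default_na=False)
        de_ids = set(de_genes[0]) | set(de_genes[1])
        de_mir_ids = set(de_mirnas[0]) | set(de_mirnas[1])
        elements = pd.concat(
            [
                genes_bed[genes_bed["element_id"].isin(de_ids)],
                mirnas_bed[mirnas_bed["element_id"].isin(de_mir_ids)],
                snps_bed,
            ],
            ignore_index=True,
        )
        found = cl.detect_clusters(elements, config.max_gap_bp,
                                   config.high_density_min)
        table = cl.clusters_table(found)
        save(table, "clusters.tsv", index=False)
        report.counts["n_clusters"] = len(found)
        report.counts["n_high_density"] = int(
            sum(c.high_density and not c.excluded for c in found)
        )
        note(f"clusters: {len(found)} total, "
             f"{report.counts['n_high_density']} high-density retained")
        save(cl.nearest_genes(snps_bed, genes_bed), "snp_nearest_genes.tsv",
             index=False)
        if config.chrom_sizes:
            sizes = pd.read_csv(config.chrom_sizes, sep="\t")
            gene_counts = genes_bed.groupby("chrom").size()
            save(cl.chromosome_density(elements, sizes, gene_counts),
                 "chromosome_density.tsv", index=False)
        records, summary_counts = cl.host_gene_coexpression(
            mirnas_bed, mirna_table, gene_table,
            fdr=config.fdr, lfc=config.lfc, mirna_p=config.mirna_p,
        )
        save(pd.DataFrame([asdict(r) for r in records]),
             "host_coexpression.tsv", index=False)
        report.counts.update(
            {f"host_{k}": v for k, v in summary_counts.items()}
        )
        note(f"host co-expression: {summary_counts}")

    report_path = out / "run_report.json"
    report_path.write_text(
        json.dumps(
            {"manifest": report.manifest, "counts": report.counts,
             "log": report.log},
            indent=1,
            sort_keys=True,
        )
    )
    return report
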