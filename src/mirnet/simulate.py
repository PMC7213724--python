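"""Synthetic matched mRNA/miRNA dataset generator with planted ground truth.

Emulates a small two-group tissue study (atrial fibrillation cases vs
sinus-rhythm controls): negative-binomial RNA-seq counts with planted
log2 fold changes, Gaussian log2 microarray intensities with planted
shifts, a miRNA->gene target-prediction table containing the planted
regulatory pairs plus decoys, and BED-like genomic annotations in which
some differentially expressed elements are co-located in tight clusters.

Every random draw flows from a single integer seed, so a fixed
(config, seed) pair reproduces the dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

MAX_CLUSTER_GAP_BP = 20_000
SCATTER_MIN_GAP_BP = 100_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the simulated case-control experiment.

    Defaults mirror the emulated study: 6 cases vs 6 controls, a few
    hundred genes with a planted DE fraction, strong planted fold changes
    (|log2FC| in [1.5, 3]) and tightly anti-correlated regulator-target
    pairs (pair_effect = fraction of the target's within-group log-scale
    variance explained by its regulator miRNA).
    """

    n_group1: int = 6  # cases (AF)
    n_group2: int = 6  # controls (SR)
    n_genes: int = 300
    n_mirnas: int = 60
    n_de_genes: int = 40
    n_de_mirnas: int = 12
    lfc_range: tuple[float, float] = (1.5, 3.0)
    nb_dispersion: float = 0.05  # variance = mu + alpha * mu^2
    mirna_sd: float = 0.25  # per-miRNA log2 intensity SD
    n_true_pairs: int = 30
    pair_effect: float = 0.9
    prediction_noise: int = 200  # decoy prediction rows
    n_chromosomes: int = 3
    chrom_length_bp: int = 50_000_000
    n_planted_clusters: int = 2
    cluster_span_bp: int = 60_000
    n_snps: int = 40
    n_hosted_mirnas: int = 8  # miRNAs placed inside a host gene
    coupling_sd: float = 0.5  # within-group log2 SD budget of paired targets
    outlier_sample: bool = False  # inflate one control's noise (QC exercise)
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_group1": self.n_group1,
            "n_group2": self.n_group2,
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be strictly positive")
        if self.mirna_sd <= 0:
            raise ValueError("mirna_sd must be strictly positive")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if not 0 <= self.n_de_mirnas <= self.n_mirnas:
            raise ValueError("n_de_mirnas must lie in [0, n_mirnas]")
        if not 0 < self.lfc_range[0] <= self.lfc_range[1]:
            raise ValueError("lfc_range must satisfy 0 < lo <= hi")
        if not 0 <= self.pair_effect <= 1:
            raise ValueError("pair_effect must lie in [0, 1]")
        if self.n_true_pairs > self.n_de_genes:
            raise ValueError("n_true_pairs cannot exceed n_de_genes")
        if self.n_true_pairs > 0 and self.n_de_mirnas == 0:
            raise ValueError("true pairs require at least one DE miRNA")
        if self.n_snps < 0 or self.prediction_noise < 0:
            raise ValueError("counts must be non-negative")
        if self.n_planted_clusters < 0:
            raise ValueError("n_planted_clusters must be non-negative")
        if self.cluster_span_bp >= self.chrom_length_bp:
            raise ValueError("cluster span exceeds chromosome length")
        if self.n_hosted_mirnas > self.n_mirnas:
            raise ValueError("n_hosted_mirnas cannot exceed n_mirnas")


@dataclass
class GroundTruth:
    """Planted signals: DE effects, regulatory pairs, genomic clusters."""

    de_genes: dict[str, float] = field(default_factory=dict)  # id -> log2FC
    de_mirnas: dict[str, float] = field(default_factory=dict)  # id -> shift
    true_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_clusters: list[dict] = field(default_factory=list)
    outlier_sample_id: str | None = None


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame  # genes x samples, integers
    mirna_intensity: pd.DataFrame  # miRNAs x samples, log2 scale
    samples: pd.DataFrame  # sample_id, group
    predictions: pd.DataFrame  # mirna_id, gene_id, region, probability, validated
    genes_bed: pd.DataFrame
    mirnas_bed: pd.DataFrame
    snps_bed: pd.DataFrame
    chrom_sizes: pd.DataFrame  # chrom, length_bp
    truth: GroundTruth


BED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "element_id",
    "element_type",
    "strand",
    "host_gene_id",
    "context",
]


def _signed_lfcs(rng: np.random.Generator, n: int, lfc_range) -> np.ndarray:
    magnitudes = rng.uniform(lfc_range[0], lfc_range[1], size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    return magnitudes * signs


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full matched dataset plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n1, n2 = config.n_group1, config.n_group2
    samples = [f"AF{i + 1:02d}" for i in range(n1)] + [
        f"SR{i + 1:02d}" for i in range(n2)
    ]
    is_case = np.array([1.0] * n1 + [0.0] * n2)
    sample_sheet = pd.DataFrame(
        {"sample_id": samples, "group": ["AF"] * n1 + ["SR"] * n2}
    )

    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirnas)]

    # ---- planted DE assignments -------------------------------------------
    de_gene_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    de_mirna_idx = rng.choice(config.n_mirnas, size=config.n_de_mirnas, replace=False)
    gene_lfc = np.zeros(config.n_genes)
    gene_lfc[de_gene_idx] = _signed_lfcs(rng, config.n_de_genes, config.lfc_range)
    mirna_shift = np.zeros(config.n_mirnas)
    mirna_shift[de_mirna_idx] = _signed_lfcs(rng, config.n_de_mirnas, config.lfc_range)

    # true pairs: distinct DE target genes, DE miRNAs cycled; the target's
    # planted log2FC is forced opposite in sign to its regulator's shift
    true_pairs: list[tuple[int, int]] = []
    for k in range(config.n_true_pairs):
        g = de_gene_idx[k]
        m = de_mirna_idx[k % config.n_de_mirnas]
        gene_lfc[g] = -np.sign(mirna_shift[m]) * abs(gene_lfc[g])
        true_pairs.append((m, g))

    # ---- miRNA intensity matrix (log2 scale) ------------------------------
    mirna_base = rng.uniform(6.0, 13.0, size=config.n_mirnas)
    noise_sd = np.full(len(samples), config.mirna_sd)
    outlier_id: str | None = None
    if config.outlier_sample:
        outlier_id = samples[-1]
        noise_sd[-1] *= 6.0
    intensity = (
        mirna_base[:, None]
        + mirna_shift[:, None] * is_case[None, :]
        + rng.normal(0.0, 1.0, size=(config.n_mirnas, len(samples))) * noise_sd
    )
    mirna_df = pd.DataFrame(intensity, index=mirna_ids, columns=samples)
    mirna_df.index.name = "mirna_id"

    # ---- gene count matrix -------------------------------------------------
    base_mean = rng.lognormal(mean=np.log(300.0), sigma=1.0, size=config.n_genes)
    # paired targets get comfortably expressed base means so the regulator
    # signal is not swamped by counting noise
    for _, g in true_pairs:
        base_mean[g] = rng.lognormal(mean=np.log(800.0), sigma=0.5)

    log2_mu = np.log2(base_mean)[:, None] + gene_lfc[:, None] * is_case[None, :]

    # regulator->target coupling on the log-mean: the within-group residual
    # of the miRNA intensity depresses the target, scaled so pair_effect of
    # the target's within-group log variance is regulator-driven
    pe = config.pair_effect
    for m, g in true_pairs:
        x = intensity[m]
        resid = x.copy()
        resid[: n1] -= x[:n1].mean()
        resid[n1:] -= x[n1:].mean()
        sd = resid.std()
        z = resid / sd if sd > 0 else np.zeros_like(resid)
        w = rng.normal(0.0, 1.0, size=len(samples))
        log2_mu[g] += config.coupling_sd * (
            -np.sqrt(pe) * z + np.sqrt(1.0 - pe) * w
        )

    mu = np.power(2.0, log2_mu)
    if config.outlier_sample:
        mu[:, -1] *= np.power(2.0, rng.normal(0.0, 1.5, size=config.n_genes))
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    counts_df.index.name = "gene_id"

    # ---- target prediction table ------------------------------------------
    rows: list[tuple[str, str, str, float, bool]] = []
    taken = set()
    for m, g in true_pairs:
        rows.append(
            (
                mirna_ids[m],
                gene_ids[g],
                "3UTR",
                float(rng.uniform(0.9501, 1.0)),
                bool(rng.random() < 0.2),
            )
        )
        taken.add((m, g))
    non_de_genes = [i for i in range(config.n_genes) if gene_lfc[i] == 0]
    n_decoys = config.prediction_noise
    kinds = rng.choice(3, size=n_decoys)
    for kind in kinds:
        for _ in range(100):
            m = int(rng.integers(config.n_mirnas))
            if kind == 0:  # sub-threshold probability
                g = int(rng.integers(config.n_genes))
                row = (mirna_ids[m], gene_ids[g], "3UTR",
                       float(rng.uniform(0.5, 0.95)), False)
            elif kind == 1:  # wrong binding region
                g = int(rng.integers(config.n_genes))
                row = (mirna_ids[m], gene_ids[g], "CDS",
                       float(rng.uniform(0.9501, 1.0)), False)
            else:  # confident call on a non-DE target
                if not non_de_genes:
                    continue
                g = int(non_de_genes[rng.integers(len(non_de_genes))])
                row = (mirna_ids[m], gene_ids[g], "3UTR",
                       float(rng.uniform(0.9501, 1.0)), False)
            if (m, g) not in taken:
                taken.add((m, g))
                rows.append(row)
                break
    predictions = pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "region", "binding_probability", "validated"],
    )

    # ---- genomic annotations ----------------------------------------------
    genes_bed, mirnas_bed, snps_bed, planted_clusters = _place_elements(
        config, rng, gene_ids, mirna_ids, gene_lfc, mirna_shift
    )
    chrom_sizes = pd.DataFrame(
        {
            "chrom": [f"chr{i + 1}" for i in range(config.n_chromosomes)],
            "length_bp": [config.chrom_length_bp] * config.n_chromosomes,
        }
    )

    truth = GroundTruth(
        de_genes={gene_ids[i]: float(gene_lfc[i]) for i in sorted(de_gene_idx)},
        de_mirnas={mirna_ids[i]: float(mirna_shift[i]) for i in sorted(de_mirna_idx)},
        true_pairs=[(mirna_ids[m], gene_ids[g]) for m, g in true_pairs],
        planted_clusters=planted_clusters,
        outlier_sample_id=outlier_id,
    )
    return SyntheticDataset(
        counts=counts_df,
        mirna_intensity=mirna_df,
        samples=sample_sheet,
        predictions=predictions,
        genes_bed=genes_bed,
        mirnas_bed=mirnas_bed,
        snps_bed=snps_bed,
        chrom_sizes=chrom_sizes,
        truth=truth,
    )


def _place_elements(config, rng, gene_ids, mirna_ids, gene_lfc, mirna_shift):
    """Lay out genes, miRNAs and SNPs on the simulated chromosomes.

    Planted clusters pack DE genes, DE miRNAs and SNPs with inter-element
    gaps well under the 20-kbp clustering threshold; every other element is
    scattered with >= 100-kbp gaps so no spurious cluster can form.
    """
    n_chrom = config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    de_genes = [i for i in range(config.n_genes) if gene_lfc[i] != 0]
    de_mirnas = [i for i in range(config.n_mirnas) if mirna_shift[i] != 0]

    gene_rows: dict[int, list] = {}
    mirna_rows: dict[int, list] = {}
    snp_rows: list[list] = []
    planted_clusters: list[dict] = []

    # -- planted clusters: 2 DE genes + 2 DE miRNAs + 2 SNPs each -----------
    used_genes: set[int] = set()
    used_mirnas: set[int] = set()
    snp_counter = 0
    cluster_starts: list[int] = []
    for c in range(config.n_planted_clusters):
        chrom_i = c % n_chrom
        chrom = chroms[chrom_i]
        members: list[tuple[str, str, int]] = []  # (id, type, length)
        # prefer DE members (so the downstream locus analysis can see the
        # cluster); fall back to non-DE elements in null configurations
        gene_pool = [g for g in de_genes if g not in used_genes] + [
            g for g in range(config.n_genes)
            if gene_lfc[g] == 0 and g not in used_genes
        ]
        mirna_pool = [m for m in de_mirnas if m not in used_mirnas] + [
            m for m in range(config.n_mirnas)
            if mirna_shift[m] == 0 and m not in used_mirnas
        ]
        picked_genes = gene_pool[:2]
        picked_mirnas = mirna_pool[:2]
        if len(picked_genes) < 2 or len(picked_mirnas) < 2:
            raise ValueError(
                "not enough distinct genes/miRNAs to populate planted clusters"
            )
        used_genes.update(picked_genes)
        used_mirnas.update(picked_mirnas)
        for g in picked_genes:
            members.append((gene_ids[g], "gene", int(rng.integers(3_000, 8_000))))
        for m in picked_mirnas:
            members.append((mirna_ids[m], "mirna", 100))
        for _ in range(2):
            snp_counter += 1
            members.append((f"rs{100000 + snp_counter}", "snp", 1))
        rng.shuffle(members)
        n_gaps = len(members) - 1
        max_gap = min(
            MAX_CLUSTER_GAP_BP - 1_000, max(config.cluster_span_bp // n_gaps, 2_000)
        )
        gaps = rng.integers(500, max_gap, size=n_gaps)
        span = sum(length for _, _, length in members) + int(gaps.sum())
        if span >= config.chrom_length_bp:
            raise ValueError("cluster span exceeds chromosome length")
        start = int(
            rng.integers(1_000_000, config.chrom_length_bp - span - 1_000_000)
        )
        cluster_starts.append(start)
        pos = start
        member_ids = []
        for k, (elem_id, elem_type, length) in enumerate(members):
            row = [chrom, pos, pos + length, elem_id, elem_type, "+", ".", "."]
            if elem_type == "gene":
                gene_rows[gene_ids.index(elem_id)] = row
            elif elem_type == "mirna":
                mirna_rows[mirna_ids.index(elem_id)] = row
            else:
                snp_rows.append(row)
            member_ids.append(elem_id)
            pos += length + (int(gaps[k]) if k < n_gaps else 0)
        planted_clusters.append({"chromosome": chrom, "members": member_ids})

    # -- hosted miRNAs: placed inside a (scattered) host gene later ---------
    free_mirnas = [i for i in range(config.n_mirnas) if i not in mirna_rows]
    # alternate DE / non-DE so host co-expression analysis sees both
    de_free = [i for i in free_mirnas if mirna_shift[i] != 0]
    nde_free = [i for i in free_mirnas if mirna_shift[i] == 0]
    hosted: list[int] = []
    while len(hosted) < min(config.n_hosted_mirnas, len(free_mirnas)):
        pool = de_free if (len(hosted) % 2 == 0 and de_free) else nde_free
        if not pool:
            pool = de_free or nde_free
        hosted.append(pool.pop(0))

    # -- scatter everything else with >= 100-kbp spacing ---------------------
    cursors = {c: int(rng.integers(0, 50_000)) for c in chroms}
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for c, start in zip(
        [chroms[i % n_chrom] for i in range(config.n_planted_clusters)],
        cluster_starts,
    ):
        reserved[c].append((start - SCATTER_MIN_GAP_BP, start + config.cluster_span_bp
                            + 3 * SCATTER_MIN_GAP_BP))

    def advance(chrom: str, length: int) -> int:
        pos = cursors[chrom] + SCATTER_MIN_GAP_BP + int(rng.integers(0, 20_000))
        for lo, hi in reserved[chrom]:
            if pos < hi and pos + length > lo:
                pos = hi
        if pos + length >= config.chrom_length_bp:
            raise ValueError(
                f"infeasible placement: {chrom} exhausted at {pos} bp; "
                "increase chrom_length_bp or n_chromosomes"
            )
        cursors[chrom] = pos + length
        return pos

    order = 0
    for i in range(config.n_genes):
        if i in gene_rows:
            continue
        chrom = chroms[order % n_chrom]
        order += 1
        length = int(rng.integers(3_000, 30_000))
        pos = advance(chrom, length)
        gene_rows[i] = [chrom, pos, pos + length, gene_ids[i], "gene", "+", ".", "."]

    host_pool = [i for i in range(config.n_genes) if gene_rows[i][2] - gene_rows[i][1]
                 >= 3_000 and i not in used_genes]
    for j, m in enumerate(hosted):
        host = host_pool[int(rng.integers(len(host_pool)))]
        hrow = gene_rows[host]
        start = int(rng.integers(hrow[1], hrow[2] - 100))
        context = "intronic" if rng.random() < 0.75 else "exonic"
        mirna_rows[m] = [hrow[0], start, start + 100, mirna_ids[m], "mirna", "+",
                         gene_ids[host], context]
    for i in range(config.n_mirnas):
        if i in mirna_rows:
            continue
        chrom = chroms[order % n_chrom]
        order += 1
        pos = advance(chrom, 100)
        mirna_rows[i] = [chrom, pos, pos + 100, mirna_ids[i], "mirna", "+", ".",
                         "intergenic"]
    while snp_counter < config.n_snps:
        snp_counter += 1
        chrom = chroms[order % n_chrom]
        order += 1
        pos = advance(chrom, 1)
        snp_rows.append([chrom, pos, pos + 1, f"rs{100000 + snp_counter}", "snp",
                         "+", ".", "."])

    genes_bed = pd.DataFrame(
        [gene_rows[i] for i in range(config.n_genes)], columns=BED_COLUMNS
    )
    mirnas_bed = pd.DataFrame(
        [mirna_rows[i] for i in range(config.n_mirnas)], columns=BED_COLUMNS
    )
    snps_bed = pd.DataFrame(snp_rows, columns=BED_COLUMNS)
    return genes_bed, mirnas_bed, snps_bed, planted_clusters


# ---------------------------------------------------------------------------
# on-disk representation

_FILES = {
    "counts": "counts.tsv",
    "mirna_intensity": "mirna_intensity.tsv",
    "samples": "samples.tsv",
    "predictions": "predictions.tsv",
    "genes_bed": "genes.bed",
    "mirnas_bed": "mirnas.bed",
    "snps_bed": "snps.bed",
    "chrom_sizes": "chrom_sizes.tsv",
    "truth": "truth.json",
}


def write_dataset(
    dataset: SyntheticDataset, directory: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Write every table as TSV/BED/JSON; refuses to clobber without flag."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in _FILES.items()}
    if not overwrite:
        existing = [p.name for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing}; pass overwrite=True"
            )
    dataset.counts.to_csv(paths["counts"], sep="\t")
    dataset.mirna_intensity.to_csv(paths["mirna_intensity"], sep="\t")
    dataset.samples.to_csv(paths["samples"], sep="\t", index=False)
    dataset.predictions.to_csv(paths["predictions"], sep="\t", index=False)
    for key in ("genes_bed", "mirnas_bed", "snps_bed"):
        getattr(dataset, key).to_csv(paths[key], sep="\t", index=False)
    dataset.chrom_sizes.to_csv(paths["chrom_sizes"], sep="\t", index=False)
    truth = asdict(dataset.truth)
    truth["true_pairs"] = [list(p) for p in truth["true_pairs"]]
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset` (exact round trip)."""
    directory = Path(directory)
    paths = {key: directory / name for key, name in _FILES.items()}
    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    mirna = pd.read_csv(paths["mirna_intensity"], sep="\t", index_col=0)
    samples = pd.read_csv(paths["samples"], sep="\t")
    predictions = pd.read_csv(paths["predictions"], sep="\t")
    if predictions.empty:
        predictions = predictions.astype(
            {"binding_probability": float, "validated": bool}, errors="ignore"
        )
    beds = {
        key: pd.read_csv(paths[key], sep="\t", keep_default_na=False)
        for key in ("genes_bed", "mirnas_bed", "snps_bed")
    }
    chrom_sizes = pd.read_csv(paths["chrom_sizes"], sep="\t")
    raw = json.loads(paths["truth"].read_text())
    truth = GroundTruth(
        de_genes=raw["de_genes"],
        de_mirnas=raw["de_mirnas"],
        true_pairs=[tuple(p) for p in raw["true_pairs"]],
        planted_clusters=raw["planted_clusters"],
        outlier_sample_id=raw.get("outlier_sample_id"),
    )
    return SyntheticDataset(
        counts=counts,
        mirna_intensity=mirna,
        samples=samples,
        predictions=predictions,
        genes_bed=beds["genes_bed"],
        mirnas_bed=beds["mirnas_bed"],
        snps_bed=beds["snps_bed"],
        chrom_sizes=chrom_sizes,
        truth=truth,
    )
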