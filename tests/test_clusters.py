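"""Positional clustering, nearest genes, densities, host co-expression."""

import numpy as np
import pandas as pd
import pytest

from conftest import cluster_oracle
from mirnet import clusters as cl
from mirnet import diffexpr as de
from mirnet.clusters import detect_clusters, nearest_genes

BED = ["chrom", "start", "end", "element_id", "element_type"]


def _elements(rows):
    return pd.DataFrame(rows, columns=BED)


@pytest.fixture()
def cardiac_locus():
    """Six mixed elements laid out with successive gaps under 20 kbp,
    mimicking a myosin-gene/miR-208/SNP susceptibility locus on chr14."""
    return _elements(
        [
            ("chr14", 100_000, 100_001, "rs_a", "snp"),
            ("chr14", 112_000, 112_001, "rs_b", "snp"),
            ("chr14", 120_000, 146_000, "MYH7", "gene"),
            ("chr14", 150_000, 150_100, "miR-208b", "mirna"),
            ("chr14", 160_000, 186_000, "MYH6", "gene"),
            ("chr14", 190_000, 190_100, "miR-208a", "mirna"),
        ]
    )


class TestDetectClusters:
    def test_mixed_six_element_locus_is_one_high_density_cluster(
        self, cardiac_locus
    ):
        found = detect_clusters(cardiac_locus)
        assert len(found) == 1
        c = found[0]
        assert c.size == 6
        assert c.high_density and not c.snp_only and not c.excluded
        assert c.member_ids[0] == "rs_a" and c.member_ids[-1] == "miR-208a"

    def test_snp_only_high_density_cluster_is_excluded(self):
        rows = [("chr1", 1000 + 5000 * i, 1001 + 5000 * i, f"rs{i}", "snp")
                for i in range(5)]
        found = detect_clusters(_elements(rows))
        assert len(found) == 1
        assert found[0].high_density and found[0].snp_only and found[0].excluded

    def test_small_snp_only_cluster_kept_but_flagged(self):
        rows = [("chr1", 1000, 1001, "rs1", "snp"),
                ("chr1", 6000, 6001, "rs2", "snp")]
        found = detect_clusters(_elements(rows))
        assert found[0].snp_only and not found[0].excluded

    @pytest.mark.parametrize("gap,expected", [(20_000, 1), (20_001, 0)])
    def test_gap_boundary_inclusive_at_20kbp(self, gap, expected):
        rows = [("chr1", 0, 100, "a", "gene"),
                ("chr1", 100 + gap, 300 + gap, "b", "gene")]
        assert len(detect_clusters(_elements(rows))) == expected

    def test_nested_interval_cannot_break_a_chain(self):
        # a long gene spans a short miRNA; the next element joins through
        # the running maximum end, not the nested interval's end
        rows = [
            ("chr2", 0, 100_000, "big", "gene"),
            ("chr2", 1_000, 1_100, "nested", "mirna"),
            ("chr2", 110_000, 110_001, "rs1", "snp"),
        ]
        found = detect_clusters(_elements(rows))
        assert len(found) == 1 and found[0].size == 3

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(2, 50))
            rows = []
            for i in range(n):
                start = int(rng.integers(0, 400_000))
                length = int(rng.integers(1, 30_000))
                rows.append(
                    (f"chr{rng.integers(1, 3)}", start, start + length,
                     f"e{i}", "gene")
                )
            elements = _elements(rows)
            got = {
                frozenset(c.member_ids)
                for c in detect_clusters(elements, max_gap_bp=15_000)
            }
            assert got == cluster_oracle(elements, 15_000)

    def test_row_order_and_shift_invariance(self, cardiac_locus):
        base = [frozenset(c.member_ids) for c in detect_clusters(cardiac_locus)]
        shuffled = cardiac_locus.sample(frac=1.0, random_state=3)
        assert [frozenset(c.member_ids)
                for c in detect_clusters(shuffled)] == base
        shifted = cardiac_locus.assign(
            start=cardiac_locus["start"] + 1_000_000,
            end=cardiac_locus["end"] + 1_000_000,
        )
        assert [frozenset(c.member_ids)
                for c in detect_clusters(shifted)] == base

    def test_partition_property(self):
        rng = np.random.default_rng(29)
        starts = np.sort(rng.integers(0, 300_000, size=40))
        elements = _elements(
            [("chr1", int(s), int(s) + 100, f"e{i}", "gene")
             for i, s in enumerate(starts)]
        )
        found = detect_clusters(elements)
        members = [m for c in found for m in c.member_ids]
        assert len(members) == len(set(members))  # at most one cluster each
        assert set(members) <= set(elements["element_id"])

    def test_gap_monotonicity_never_splits(self):
        rng = np.random.default_rng(31)
        starts = np.sort(rng.integers(0, 500_000, size=30))
        elements = _elements(
            [("chr1", int(s), int(s) + 50, f"e{i}", "gene")
             for i, s in enumerate(starts)]
        )
        narrow = detect_clusters(elements, max_gap_bp=10_000)
        wide = {frozenset(c.member_ids)
                for c in detect_clusters(elements, max_gap_bp=40_000)}
        for cluster in narrow:
            assert any(frozenset(cluster.member_ids) <= w for w in wide)

    def test_malformed_intervals_rejected(self):
        with pytest.raises(ValueError):
            detect_clusters(_elements([("chr1", 100, 100, "x", "gene")]))


class TestNearestGenes:
    GENES = _elements(
        [("chr1", 1_000, 2_000, "gA", "gene"),
         ("chr1", 10_000, 12_000, "gB", "gene"),
         ("chr2", 500, 900, "gC", "gene")]
    )

    def test_snp_inside_gene_distance_zero(self):
        snps = _elements([("chr1", 1_500, 1_501, "rs1", "snp")])
        out = nearest_genes(snps, self.GENES)
        assert out.iloc[0]["nearest_genes"] == "gA"
        assert out.iloc[0]["distance_bp"] == 0

    def test_midway_snp_returns_both_flanking_genes(self):
        genes = _elements(
            [("chr1", 1_000, 2_000, "gA", "gene"),
             ("chr1", 10_001, 12_000, "gB", "gene")]
        )
        # SNP [6000, 6001): gap to gA end = 4000 = gap to gB start
        snps = _elements([("chr1", 6_000, 6_001, "rs1", "snp")])
        out = nearest_genes(snps, genes)
        assert out.iloc[0]["nearest_genes"] == "gA,gB"
        assert out.iloc[0]["distance_bp"] == 4_000

    def test_geneless_chromosome_unassigned(self):
        snps = _elements([("chr9", 100, 101, "rs1", "snp")])
        out = nearest_genes(snps, self.GENES)
        assert out.iloc[0]["nearest_genes"] == ""
        assert pd.isna(out.iloc[0]["distance_bp"])

    def test_max_distance_cap(self):
        snps = _elements([("chr1", 100_000, 100_001, "rs1", "snp")])
        capped = nearest_genes(snps, self.GENES, max_distance_bp=1_000)
        assert capped.iloc[0]["nearest_genes"] == ""

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(37)
        genes = _elements(
            [("chr1", int(s), int(s) + int(rng.integers(100, 5_000)),
              f"g{i}", "gene")
             for i, s in enumerate(rng.integers(0, 200_000, size=10))]
        )
        snps = _elements(
            [("chr1", int(p), int(p) + 1, f"rs{i}", "snp")
             for i, p in enumerate(rng.integers(0, 220_000, size=30))]
        )
        out = nearest_genes(snps, genes).set_index("snp_id")
        for snp in snps.itertuples(index=False):
            dists = {}
            for g in genes.itertuples(index=False):
                if snp.start < g.end and g.start < snp.end:
                    d = 0
                else:
                    d = max(g.start - snp.end, snp.start - g.end)
                dists[g.element_id] = d
            best = min(dists.values())
            expected = ",".join(sorted(k for k, v in dists.items()
                                       if v == best))
            assert out.loc[snp.element_id, "nearest_genes"] == expected
            assert out.loc[snp.element_id, "distance_bp"] == best


class TestChromosomeDensity:
    SIZES = pd.DataFrame({"chrom": ["chr1", "chr2"],
                          "length_bp": [50_000_000, 100_000_000]})

    def test_per_mbp_arithmetic(self):
        elements = _elements(
            [("chr1", i * 1000, i * 1000 + 10, f"e{i}", "gene")
             for i in range(10)]
        )
        out = cl.chromosome_density(elements, self.SIZES,
                                    {"chr1": 5, "chr2": 3})
        row = out[out["chrom"] == "chr1"].iloc[0]
        assert row["per_mbp"] == pytest.approx(0.2)
        assert row["per_gene"] == pytest.approx(2.0)

    def test_empty_chromosome_reports_zero(self):
        out = cl.chromosome_density(_elements([]), self.SIZES,
                                    {"chr1": 5, "chr2": 3})
        assert (out["n_elements"] == 0).all()
        assert (out["per_mbp"] == 0).all()

    def test_doubling_sizes_halves_per_mbp(self):
        elements = _elements(
            [("chr1", i * 1000, i * 1000 + 10, f"e{i}", "gene")
             for i in range(8)]
        )
        doubled = self.SIZES.assign(length_bp=self.SIZES["length_bp"] * 2)
        a = cl.chromosome_density(elements, self.SIZES, {"chr1": 1})
        b = cl.chromosome_density(elements, doubled, {"chr1": 1})
        np.testing.assert_allclose(b["per_mbp"], a["per_mbp"] / 2)
        assert (a["n_elements"] == b["n_elements"]).all()

    def test_zero_size_chromosome_rejected(self):
        bad = pd.DataFrame({"chrom": ["chr1"], "length_bp": [0]})
        with pytest.raises(ValueError):
            cl.chromosome_density(_elements([]), bad, {})


def _de_table(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "log2FC", "p_raw", "p_adj"])
    return df.set_index("feature_id")


class TestHostCoexpression:
    MIRNA_BED = pd.DataFrame(
        [
            ("chr1", 100, 200, "miR-in", "mirna", "+", "HOST1", "intronic"),
            ("chr1", 300, 400, "miR-ex", "mirna", "+", "HOST2", "exonic"),
            ("chr1", 500, 600, "miR-inter", "mirna", "+", ".", "intergenic"),
            ("chr1", 700, 800, "miR-lost", "mirna", "+", "GONE", "intronic"),
        ],
        columns=["chrom", "start", "end", "element_id", "element_type",
                 "strand", "host_gene_id", "context"],
    )

    def test_rule_application_and_domain_restriction(self):
        mirna_table = _de_table(
            [("miR-in", -1.2, 0.001, 0.01),
             ("miR-ex", 2.0, 0.002, 0.01),
             ("miR-inter", 1.0, 0.001, 0.01),
             ("miR-lost", 1.0, 0.001, 0.01)]
        )
        gene_table = _de_table(
            [("HOST1", -0.8, 0.01, 0.2),   # same direction, not significant
             ("HOST2", 2.4, 0.0001, 0.001)]  # same direction, significant
        )
        records, summary = cl.host_gene_coexpression(
            self.MIRNA_BED, mirna_table, gene_table
        )
        by_id = {r.mirna_id: r for r in records}
        assert set(by_id) == {"miR-in", "miR-ex"}  # intergenic/lost skipped
        assert by_id["miR-in"].same_direction
        assert not by_id["miR-in"].both_significant
        assert by_id["miR-ex"].same_direction
        assert by_id["miR-ex"].both_significant
        assert summary == {"n_hosted": 2, "n_same_direction": 2,
                           "n_both_significant": 1}

    def test_non_significant_mirna_produces_no_record(self):
        mirna_table = _de_table([("miR-in", -1.2, 0.5, 0.9)])
        gene_table = _de_table([("HOST1", -0.8, 0.01, 0.2)])
        records, summary = cl.host_gene_coexpression(
            self.MIRNA_BED, mirna_table, gene_table
        )
        assert records == [] and summary["n_hosted"] == 0

    def test_synthetic_planted_counts_match_truth(self, default_dataset):
        # truth-derived DE tables: planted features get p ~ 0, others p = 1
        ds = default_dataset
        truth = ds.truth
        mirna_table = _de_table(
            [(m, truth.de_mirnas.get(m, 0.0),
              1e-9 if m in truth.de_mirnas else 1.0,
              1e-6 if m in truth.de_mirnas else 1.0)
             for m in ds.mirna_intensity.index]
        )
        gene_table = _de_table(
            [(g, truth.de_genes.get(g, 0.0),
              1e-9 if g in truth.de_genes else 1.0,
              1e-6 if g in truth.de_genes else 1.0)
             for g in ds.counts.index]
        )
        records, summary = cl.host_gene_coexpression(
            ds.mirnas_bed, mirna_table, gene_table
        )
        # independent expectation straight from annotations + planted truth
        expected_hosted = expected_same = expected_both = 0
        for row in ds.mirnas_bed.itertuples(index=False):
            if row.context not in ("intronic", "exonic"):
                continue
            if row.element_id not in truth.de_mirnas:
                continue
            expected_hosted += 1
            m_lfc = truth.de_mirnas[row.element_id]
            h_lfc = truth.de_genes.get(row.host_gene_id, 0.0)
            if np.sign(m_lfc) == np.sign(h_lfc):
                expected_same += 1
            if row.host_gene_id in truth.de_genes and abs(h_lfc) > 1:
                expected_both += 1
        assert summary == {
            "n_hosted": expected_hosted,
            "n_same_direction": expected_same,
            "n_both_significant": expected_both,
        }


class TestDeIntegration:
    def test_planted_clusters_recovered_from_de_calls(self, default_dataset,
                                                      de_results):
        ds = default_dataset
        de_ids = set(de_results["de_genes"][0] + de_results["de_genes"][1])
        de_mir = set(de_results["de_mirnas"][0] + de_results["de_mirnas"][1])
        elements = pd.concat(
            [
                ds.genes_bed[ds.genes_bed["element_id"].isin(de_ids)],
                ds.mirnas_bed[ds.mirnas_bed["element_id"].isin(de_mir)],
                ds.snps_bed,
            ],
            ignore_index=True,
        )
        found = detect_clusters(elements)
        high = [c for c in found if c.high_density and not c.excluded]
        planted = [set(c["members"]) for c in ds.truth.planted_clusters]
        for members in planted:
            assert any(members <= set(c.member_ids) for c in high)
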