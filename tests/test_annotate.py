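import math

import numpy as np
import pytest
from scipy.stats import chi2, fisher_exact

from aimkit.annotate import (
    CATEGORIES,
    GeneModel,
    Transcript,
    WindowConfig,
    category_counts,
    classify_regions,
    fisher_exact_2x2,
    platform_overlap,
    read_gtf,
    read_refgene,
    region_enrichment,
    window_density,
)
from aimkit.model import ArrayManifest, VariantRecord

from .oracles import fisher_two_sided_oracle


def var(pos, chrom="1", vid=None):
    return VariantRecord(chrom, pos, vid or f"v{pos}", "A", ("G",))


@pytest.fixture
def toy_model():
    # one coding gene chr1:[1000,2000) CDS [1200,1800)
    # exons [1000,1400) and [1600,2000)
    tx = Transcript(
        gene="GENE1",
        chrom="1",
        strand="+",
        start=1000,
        end=2000,
        cds_start=1200,
        cds_end=1800,
        exons=((1000, 1400), (1600, 2000)),
    )
    return GeneModel([tx], flank=1000)


class TestClassifyRegions:
    def test_exonic(self, toy_model):
        # 0-based 1300 = 1-based 1301, inside CDS within exon 1
        calls = classify_regions([var(1301)], toy_model)
        assert calls[0].category == "exonic"
        assert calls[0].gene == "GENE1"

    def test_intronic(self, toy_model):
        assert classify_regions([var(1551)], toy_model)[0].category == "intronic"

    def test_splicing_window(self, toy_model):
        # 0-based 1400 is the first intronic base after exon 1
        assert classify_regions([var(1401)], toy_model)[0].category == "splicing"
        assert classify_regions([var(1402)], toy_model)[0].category == "splicing"
        assert classify_regions([var(1403)], toy_model)[0].category == "intronic"

    def test_utrs(self, toy_model):
        assert classify_regions([var(1101)], toy_model)[0].category == "5'UTR"
        assert classify_regions([var(1901)], toy_model)[0].category == "3'UTR"

    def test_upstream_flank_rule(self, toy_model):
        # 500 bp before transcript start on + strand
        assert classify_regions([var(501)], toy_model)[0].category == "upstream"
        small = GeneModel(toy_model.transcripts, flank=100)
        assert classify_regions([var(501)], small)[0].category == "intergenic"

    def test_downstream(self, toy_model):
        assert classify_regions([var(2501)], toy_model)[0].category == "downstream"

    def test_minus_strand_flanks_swap(self):
        tx = Transcript(
            gene="G",
            chrom="1",
            strand="-",
            start=1000,
            end=2000,
            cds_start=1200,
            cds_end=1800,
            exons=((1000, 2000),),
        )
        model = GeneModel([tx], flank=500)
        assert classify_regions([var(2101)], model)[0].category == "upstream"
        assert classify_regions([var(901)], model)[0].category == "downstream"

    def test_noncoding_transcript(self):
        tx = Transcript(
            gene="NC",
            chrom="1",
            strand="+",
            start=100,
            end=500,
            cds_start=100,
            cds_end=100,
            exons=((100, 200), (400, 500)),
        )
        model = GeneModel([tx])
        assert classify_regions([var(151)], model)[0].category == "ncRNA_exonic"
        assert classify_regions([var(301)], model)[0].category == "ncRNA_intronic"

    def test_uncovered_chromosome_warns_intergenic(self, toy_model):
        with pytest.warns(UserWarning, match="coverage"):
            calls = classify_regions([var(100, chrom="9")], toy_model)
        assert calls[0].category == "intergenic"

    def test_precedence_exonic_beats_intronic(self, toy_model):
        # second overlapping transcript whose intron covers an exonic pos
        tx2 = Transcript(
            gene="GENE2",
            chrom="1",
            strand="+",
            start=900,
            end=2100,
            cds_start=950,
            cds_end=2050,
            exons=((900, 1000), (2000, 2100)),
        )
        model = GeneModel([*toy_model.transcripts, tx2])
        call = classify_regions([var(1301)], model)[0]
        assert call.category == "exonic" and call.gene == "GENE1"

    def test_partition_property(self, toy_model):
        variants = [var(p) for p in range(1, 3002, 37)]
        calls = classify_regions(variants, toy_model)
        counts = category_counts(calls)
        assert sum(counts.values()) == len(variants)
        assert set(counts) == set(CATEGORIES)


class TestGeneModelReaders:
    def test_refgene(self, write_text):
        path = write_text(
            "genes.txt",
            "NM_1\t1\t+\t1000\t2000\t1200\t1800\t2\t1000,1600,\t1400,2000,\tGENE1\n",
        )
        txs = read_refgene(path)
        assert txs[0].gene == "GENE1"
        assert txs[0].exons == ((1000, 1400), (1600, 2000))

    def test_refgene_malformed(self, write_text):
        path = write_text("bad.txt", "NM_1\t1\t+\tnope\n")
        with pytest.raises(ValueError, match="line 1"):
            read_refgene(path)

    def test_gtf(self, write_text):
        path = write_text(
            "genes.gtf",
            """
            1\tsrc\texon\t1001\t1400\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_name "GENE1";
            1\tsrc\texon\t1601\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_name "GENE1";
            1\tsrc\tCDS\t1201\t1400\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_name "GENE1";
            1\tsrc\tCDS\t1601\t1800\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_name "GENE1";
            """,
        )
        txs = read_gtf(path)
        assert txs[0].exons == ((1000, 1400), (1600, 2000))
        assert (txs[0].cds_start, txs[0].cds_end) == (1200, 1800)
        assert txs[0].coding

    def test_transcript_validation(self):
        with pytest.raises(ValueError, match="CDS"):
            Transcript("G", "1", "+", 100, 200, 50, 150, ((100, 200),))
        with pytest.raises(ValueError, match="unsorted"):
            Transcript("G", "1", "+", 0, 300, 0, 0, ((200, 300), (0, 100)))


class TestWindowDensity:
    def test_boundary_convention(self):
        variants = [var(1), var(1_000_000), var(1_000_001)]
        df = window_density(variants, WindowConfig(), {"1": 2_000_000})
        assert list(df["count"]) == [2, 1]
        assert list(df["start"]) == [0, 1_000_000]

    def test_no_variants_all_zero(self):
        df = window_density([], WindowConfig(length=100), {"1": 350})
        assert list(df["count"]) == [0, 0, 0, 0]
        assert df["end"].iloc[-1] == 350  # partial last tile retained

    def test_totals_conserved_per_chromosome(self):
        rng = np.random.default_rng(0)
        variants = [var(int(p) + 1) for p in rng.integers(0, 10_000, size=200)]
        variants += [var(int(p) + 1, chrom="2") for p in rng.integers(0, 5_000, 77)]
        df = window_density(variants, WindowConfig(length=1000), {"1": 10_000, "2": 5_000})
        assert df[df.chrom == "1"]["count"].sum() == 200
        assert df[df.chrom == "2"]["count"].sum() == 77

    def test_beyond_length_goes_to_last_tile(self):
        with pytest.warns(UserWarning, match="beyond"):
            df = window_density([var(950)], WindowConfig(length=100), {"1": 500})
        assert df["count"].iloc[-1] == 1

    def test_uniformity_not_rejected(self):
        rng = np.random.default_rng(11)
        n = 5000
        variants = [var(int(p) + 1) for p in rng.integers(0, 10_000, size=n)]
        df = window_density(variants, WindowConfig(length=1000), {"1": 10_000})
        counts = df["count"].to_numpy()
        assert counts.sum() == n
        stat = ((counts - n / 10) ** 2 / (n / 10)).sum()
        assert stat < chi2.ppf(0.999, df=9)


class TestFisherExact:
    def test_known_table(self):
        p, odds = fisher_exact_2x2(((3, 1), (1, 3)))
        assert p == pytest.approx(0.485714, abs=1e-6)
        assert odds == pytest.approx(9.0)

    def test_one_sided_tail_matches_enumeration(self):
        # one-sided tail for [[3,1],[1,3]] is 17/70
        from scipy.stats import hypergeom

        tail = hypergeom.pmf([3, 4], 8, 4, 4).sum()
        assert tail == pytest.approx(17 / 70, abs=1e-12)

    def test_identical_proportions_p_one(self):
        res = region_enrichment({"x": 5, "y": 5}, {"x": 50, "y": 50}, "x")
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_table(self):
        p, _ = fisher_exact_2x2(((0, 10), (10, 0)))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_zero_margin(self):
        res = region_enrichment({"x": 0, "y": 5}, {"x": 0, "y": 7}, "x")
        assert res.p_value == 1.0
        assert math.isnan(res.odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(((-1, 2), (3, 4)))

    def test_matches_enumeration_small_margins(self):
        for m1 in range(0, 13):
            for m2 in range(0, 13):
                for a in range(m1 + 1):
                    for c in range(m2 + 1):
                        p, _ = fisher_exact_2x2(((a, m1 - a), (c, m2 - c)))
                        exp = fisher_two_sided_oracle(a, m1 - a, c, m2 - c)
                        assert p == pytest.approx(exp, abs=1e-12), (a, m1, c, m2)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            p, _ = fisher_exact_2x2(((a, b), (c, d)))
            assert p == pytest.approx(
                fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-9, abs=1e-12
            )


class TestPlatformOverlap:
    def test_basic_fraction(self):
        mani = ArrayManifest("ArrayA", frozenset({"rs2", "rs3", "rs9"}))
        rep = platform_overlap(["rs1", "rs2", "rs3"], [mani])
        assert rep.per_platform.loc[0, "n_matched"] == 2
        assert rep.per_platform.loc[0, "fraction"] == pytest.approx(2 / 3)

    def test_empty_overlap(self):
        mani = ArrayManifest("ArrayA", frozenset({"rsX"}))
        rep = platform_overlap(["rs1"], [mani])
        assert rep.per_platform.loc[0, "n_matched"] == 0

    def test_union_no_double_counting(self):
        m1 = ArrayManifest("A", frozenset({"rs1"}))
        m2 = ArrayManifest("B", frozenset({"rs1", "rs2"}))
        rep = platform_overlap(["rs1", "rs2", "rs3"], [m1, m2])
        assert rep.union_count == 2

    def test_position_fallback(self):
        mani = ArrayManifest(
            "A", frozenset({"chip1"}), frozenset({("1", 100)})
        )
        rep = platform_overlap(
            ["rs1", "rs2"], [mani], panel_positions=[("1", 100), ("1", 200)]
        )
        assert rep.per_platform.loc[0, "n_matched"] == 1

    def test_imputable_count(self):
        mani = ArrayManifest("A", frozenset({"rs1"}))
        rep = platform_overlap(
            ["rs1", "rs2"], [mani], imputable_ids={"rs1", "rs2", "rs9"}
        )
        assert rep.imputable_count == 2
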