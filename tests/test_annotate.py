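import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from eyemorph import annotate as ann


@pytest.fixture
def plus_gene():
    # exons 1001-1060 and 1201-1260; CDS 1031-1060 + 1201-1230 (60 bp)
    return ann.GeneModel(gene_id="gA", chrom="scf1", strand="+",
                         exons=[(1001, 1060), (1201, 1260)],
                         cds=[(1031, 1060), (1201, 1230)])


@pytest.fixture
def seqs():
    s = list("A" * 3000)
    s[1030:1033] = list("GGA")  # first CDS codon at 1031-1033 (1-based)
    return {"scf1": "".join(s)}


class TestGeneModel:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ann.GeneModel("g", "c", "+", exons=[(1, 100), (50, 200)])

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ann.GeneModel("g", "c", "+", exons=[(1, 100)], cds=[(90, 150)])

    def test_coding_ok_flags_frame(self, plus_gene):
        assert plus_gene.coding_ok
        broken = ann.GeneModel("g", "c", "+", exons=[(1, 100)], cds=[(1, 10)])
        assert not broken.coding_ok


class TestLiftover:
    def _snps(self, chrom, positions, ref="A", alt="G"):
        return pd.DataFrame({"chrom": chrom, "pos": positions,
                             "ref": ref, "alt": alt})

    def test_identity_block(self):
        blocks = pd.DataFrame([{"src_chrom": "c1", "src_start": 1,
                                "src_end": 1000, "dst_chrom": "c1",
                                "dst_offset": 1, "orientation": "+"}])
        lifted, unmapped = ann.liftover_blocks(self._snps("c1", [5, 600]), blocks)
        assert list(lifted["pos"]) == [5, 600]
        assert unmapped.empty

    def test_minus_block_arithmetic_and_complement(self):
        blocks = pd.DataFrame([{"src_chrom": "c1", "src_start": 101,
                                "src_end": 200, "dst_chrom": "scf",
                                "dst_offset": 1000, "orientation": "-"}])
        lifted, _ = ann.liftover_blocks(self._snps("c1", [101], ref="A", alt="C"),
                                        blocks)
        assert lifted["pos"].iloc[0] == 1099
        assert lifted["ref"].iloc[0] == "T"
        assert lifted["alt"].iloc[0] == "G"
        assert lifted["chrom"].iloc[0] == "scf"

    def test_unmapped_reported_not_raised(self):
        blocks = pd.DataFrame([{"src_chrom": "c1", "src_start": 1,
                                "src_end": 10, "dst_chrom": "c1",
                                "dst_offset": 1, "orientation": "+"}])
        lifted, unmapped = ann.liftover_blocks(self._snps("c1", [5, 999]), blocks)
        assert len(lifted) == 1 and len(unmapped) == 1

    def test_round_trip_identity(self):
        fwd = pd.DataFrame([{"src_chrom": "c1", "src_start": 101,
                             "src_end": 200, "dst_chrom": "scf",
                             "dst_offset": 1000, "orientation": "-"}])
        inv = pd.DataFrame([{"src_chrom": "scf", "src_start": 1000,
                             "src_end": 1099, "dst_chrom": "c1",
                             "dst_offset": 101, "orientation": "-"}])
        snps = self._snps("c1", [120, 180], ref="A", alt="C")
        there, _ = ann.liftover_blocks(snps, fwd)
        back, _ = ann.liftover_blocks(there, inv)
        assert list(back["pos"]) == list(snps["pos"])
        assert list(back["ref"]) == list(snps["ref"])


class TestAnnotateSnp:
    @pytest.mark.parametrize("pos,expected", [
        (500, "upstream"),       # 501 bp 5' of the gene start
        (1010, "utr5"),
        (1061, "splicing"),
        (1100, "intronic"),
        (1199, "splicing"),
        (1240, "utr3"),
        (1500, "downstream"),
        (2900, "intergenic"),
    ])
    def test_region_classes(self, plus_gene, seqs, pos, expected):
        out = ann.annotate_snp("scf1", pos, "A", "G", [plus_gene], seqs)
        assert out.region_class == expected
        assert (out.gene_ids == []) == (expected == "intergenic")

    def test_synonymous_third_position(self, plus_gene, seqs):
        # codon GGA -> GGG, both glycine
        out = ann.annotate_snp("scf1", 1033, "A", "G", [plus_gene], seqs)
        assert out.region_class == "exonic_synonymous"

    def test_nonsynonymous_first_position(self, plus_gene, seqs):
        # GGA (Gly) -> AGA (Arg)
        out = ann.annotate_snp("scf1", 1031, "G", "A", [plus_gene], seqs)
        assert out.region_class == "exonic_nonsynonymous"

    def test_minus_strand_orientation(self, seqs):
        gene = ann.GeneModel("gB", "scf1", "-", exons=[(1001, 1300)])
        up = ann.annotate_snp("scf1", 1800, "A", "G", [gene], seqs)
        down = ann.annotate_snp("scf1", 700, "A", "G", [gene], seqs)
        assert up.region_class == "upstream"
        assert down.region_class == "downstream"

    def test_class_counts_match_region_lengths(self, plus_gene):
        # deterministic length-proportional check: classify every base
        counts = {}
        idx = {"scf1": [plus_gene]}
        for pos in range(1, 3001):
            c = ann.annotate_snp("scf1", pos, "A", "G", idx, None).region_class
            counts[c] = counts.get(c, 0) + 1
        assert counts["upstream"] == 1000      # positions 1..1000
        assert counts["utr5"] == 30
        assert counts["exonic"] == 60          # CDS without sequence context
        assert counts["splicing"] == 4         # 2 bp at each intron boundary
        assert counts["intronic"] == 136
        assert counts["utr3"] == 30
        assert counts["downstream"] == 1000
        assert counts["intergenic"] == 3000 - sum(
            v for k, v in counts.items() if k != "intergenic")

    def test_gff_parsing_matches_direct_model(self, tmp_path, plus_gene):
        gff = tmp_path / "models.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "scf1\tsrc\tgene\t1001\t1260\t.\t+\t.\tID=gA\n"
            "scf1\tsrc\tmRNA\t1001\t1260\t.\t+\t.\tID=gA.t1;Parent=gA\n"
            "scf1\tsrc\texon\t1001\t1060\t.\t+\t.\tParent=gA.t1\n"
            "scf1\tsrc\texon\t1201\t1260\t.\t+\t.\tParent=gA.t1\n"
            "scf1\tsrc\tCDS\t1031\t1060\t.\t+\t0\tParent=gA.t1\n"
            "scf1\tsrc\tCDS\t1201\t1230\t.\t+\t0\tParent=gA.t1\n"
        )
        models = ann.read_gene_models(gff)
        assert len(models) == 1
        m = models[0]
        assert m.exons == plus_gene.exons
        assert m.cds == plus_gene.cds
        assert m.strand == "+"

    def test_longest_isoform_selected(self, tmp_path):
        gff = tmp_path / "iso.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "scf1\tsrc\tgene\t100\t900\t.\t+\t.\tID=g1\n"
            "scf1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t_short;Parent=g1\n"
            "scf1\tsrc\texon\t100\t500\t.\t+\t.\tParent=t_short\n"
            "scf1\tsrc\tmRNA\t100\t900\t.\t+\t.\tID=t_long;Parent=g1\n"
            "scf1\tsrc\texon\t100\t900\t.\t+\t.\tParent=t_long\n"
        )
        models = ann.read_gene_models(gff)
        assert models[0].transcript_id == "t_long"


class TestRegionFrequency:
    def test_all_intronic(self):
        df = pd.DataFrame({"region_class": ["intronic"] * 5})
        freq = ann.region_frequency(df)
        assert freq["intronic"] == 1.0

    def test_noncoding_aggregate(self):
        df = pd.DataFrame({"region_class": ["intronic"] * 69
                           + ["exonic_synonymous"] * 31})
        freq = ann.region_frequency(df)
        assert freq["non_coding"] == pytest.approx(0.69)

    def test_proportions_sum_to_one(self, rng):
        classes = rng.choice(ann.REGION_PRECEDENCE, 200)
        freq = ann.region_frequency(pd.DataFrame({"region_class": classes}))
        assert freq.drop("non_coding").sum() == pytest.approx(1.0, abs=1e-12)


class TestOrthologs:
    def test_one_to_one(self):
        mapping = pd.DataFrame({"src": ["a", "b"], "dst": ["A", "B"]})
        targets, amb = ann.ortholog_map({"a", "b"}, mapping)
        assert targets == {"A", "B"} and amb == 0

    def test_one_to_many_with_shared_target(self):
        mapping = pd.DataFrame({
            "src": ["a", "a", "b", "b", "c", "c"],
            "dst": ["X1", "S", "X2", "S", "X3", "X4"]})
        targets, amb = ann.ortholog_map({"a", "b", "c"}, mapping)
        assert len(targets) == 5
        assert amb == 3

    def test_empty_input(self):
        mapping = pd.DataFrame({"src": ["a"], "dst": ["A"]})
        targets, amb = ann.ortholog_map(set(), mapping)
        assert targets == set()


class TestEnrichment:
    def test_yates_leq_uncorrected_and_nonnegative(self):
        ci = ann.ContingencyInput(10, 100, 100, 1000)
        res = ann.enrichment_chi2_yates(ci)
        raw = chi2_contingency(res.table, correction=False)[0]
        assert 0 <= res.statistic <= raw + 1e-12
        assert res.statistic == pytest.approx(0.0, abs=0.2)  # exact null ratio

    def test_row_column_swap_symmetry(self):
        ci = ann.ContingencyInput(30, 120, 300, 2000)
        res = ann.enrichment_chi2_yates(ci)
        swapped = chi2_contingency(res.table[::-1], correction=True)[0]
        transposed = chi2_contingency(res.table.T, correction=True)[0]
        assert res.statistic == pytest.approx(swapped, abs=1e-12)
        assert res.statistic == pytest.approx(transposed, abs=1e-12)

    def test_mode_search_reproduces_printed_statistics(self):
        cases = [("eye_dev_all", 126, 2701, 397, 37.25),
                 ("muller_b", 8, 102, 397, 7.13),
                 ("muller_c", 5, 102, 397, 0.84)]
        out = ann.enrichment_mode_search(cases)
        assert out["reproduced"].all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ann.ContingencyInput(50, 40, 100, 1000)


class TestGeneListIntersect:
    def test_disjoint(self):
        overlap, _ = ann.gene_list_intersect({"a"}, {"b"})
        assert overlap == set()

    def test_subset(self):
        overlap, _ = ann.gene_list_intersect({"a", "b", "c"}, {"a", "b"})
        assert overlap == {"a", "b"}

    def test_planted_126_of_2701(self, rng):
        genes = {f"g{i}" for i in range(2701)}
        eye = {f"g{i}" for i in range(126)} | {f"x{i}" for i in range(271)}
        overlap, _ = ann.gene_list_intersect(genes, eye)
        assert len(overlap) == 126
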