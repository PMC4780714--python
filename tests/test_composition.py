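"""Region/class composition accounting and the gene census."""

import pytest

from plastomekit.composition import (class_stats, gene_census,
                                     intron_inventory, region_stats)
from plastomekit.plastome_io import gc_percent, reverse_complement
from plastomekit.structure import detect_inverted_repeat
from plastomekit.synthetic_data import (GeneTemplate, PlastomeSpec,
                                        simulate_plastome)


class TestRegionStats:
    def test_planted_lengths_exact(self, focal_structured):
        rg, qmap, _ = focal_structured
        rows = {r.region: r for r in region_stats(rg, qmap)}
        assert rows["LSC"].length_bp == 83_921
        assert rows["SSC"].length_bp == 16_933
        assert rows["IR"].length_bp == 25_793
        assert rows["total"].length_bp == 152_440

    def test_length_percentages_sum_to_100(self, focal_structured):
        rg, qmap, _ = focal_structured
        rows = [r for r in region_stats(rg, qmap) if r.region != "total"]
        assert sum(r.length_percent_of_total for r in rows) == pytest.approx(100.0)

    def test_gc_near_target(self, focal_structured):
        rg, qmap, _ = focal_structured
        total = next(r for r in region_stats(rg, qmap) if r.region == "total")
        assert total.gc_percent == pytest.approx(38.0, abs=0.5)

    def test_all_at_genome_has_zero_gc(self):
        spec = PlastomeSpec(lsc_len=5_000, ssc_len=1_000, ir_len=2_000,
                            gene_templates=[], planted_ssrs=[],
                            planted_tandems=[], planted_dispersed=[],
                            gc_target=0.0, seed=1)
        g, _ = simulate_plastome(spec)
        rg, qmap = detect_inverted_repeat(g, min_ir_len=1_500)
        # an all-AT genome cannot support IR detection assumptions on GC, but
        # GC must be 0 in every region regardless
        for r in region_stats(rg, qmap):
            assert r.gc_percent == 0.0


class TestClassStats:
    def test_partition_sums_to_genome_length(self, focal_structured):
        rg, qmap, _ = focal_structured
        rows = class_stats(rg)
        assert sum(r.length_bp for r in rows) == len(rg)

    def test_class_lengths_match_planted_annotation(self, focal_structured):
        rg, qmap, _ = focal_structured
        rows = {r.cls: r for r in class_stats(rg)}
        n = len(rg)
        # tRNA exons planted: sum over all copies (none overlap CDS)
        trna = sum(f.length(n) for f in rg.features if f.kind == "tRNA")
        rrna = sum(f.length(n) for f in rg.features if f.kind == "rRNA")
        assert rows["tRNA"].length_bp == trna
        assert rows["rRNA"].length_bp == rrna

    def test_nested_matk_counts_as_protein_not_intron(self, focal_structured):
        rg, qmap, _ = focal_structured
        n = len(rg)
        rows = {r.cls: r for r in class_stats(rg)}
        trnk = next(f for f in rg.features if f.name == "trnK-UUU")
        matk = next(f for f in rg.features if f.name == "matK")
        raw_introns = sum(iv.length(n) for f in rg.features if not f.pseudo
                          and f.kind in ("CDS", "tRNA", "rRNA")
                          for iv in f.intron_intervals(n))
        # matK removes its span from the intron class
        assert rows["intron"].length_bp == raw_introns - matk.length(n)

    def test_featureless_genome_is_all_intergenic(self):
        from plastomekit.plastome_io import AnnotatedPlastome
        g = AnnotatedPlastome("f", "ACGT" * 1000)
        rows = {r.cls: r for r in class_stats(g)}
        assert rows["intergenic"].length_percent == 100.0

    def test_gc_invariant_under_reverse_complement(self):
        seq = "AACCGGTTACGTAGCTAG"
        assert gc_percent(seq) == pytest.approx(gc_percent(reverse_complement(seq)))


class TestGeneCensus:
    def test_gene_complement_counts(self, focal_structured):
        rg, qmap, _ = focal_structured
        c = gene_census(rg, qmap)
        assert c.total_genes == 129
        assert c.by_class == {"CDS": 84, "tRNA": 37, "rRNA": 8}
        assert c.duplicated_in_IR == 17
        assert c.unique_genes == 112
        assert c.unique_by_region == {"LSC": 82, "SSC": 13, "IR": 17}

    def test_boundary_spanning_genes(self, focal_structured):
        rg, qmap, _ = focal_structured
        c = gene_census(rg, qmap)
        assert c.boundary_spanning == ["ndhF", "rps12", "rps19", "ycf1"]

    def test_minimal_planted_duplication(self):
        tmpl = [
            GeneTemplate("g1", "CDS", "LSC", "+", (300,)),
            GeneTemplate("g2", "CDS", "LSC", "+", (200,)),
            GeneTemplate("g3", "CDS", "SSC", "+", (150,)),
            GeneTemplate("g4", "tRNA", "LSC", "+", (80,)),
            GeneTemplate("dup1", "CDS", "IR", "+", (400,)),
        ]
        spec = PlastomeSpec(lsc_len=20_000, ssc_len=5_000, ir_len=11_000,
                            gene_templates=tmpl, planted_ssrs=[],
                            planted_tandems=[], planted_dispersed=[], seed=9)
        g, _ = simulate_plastome(spec)
        rg, qmap = detect_inverted_repeat(g)
        c = gene_census(rg, qmap)
        assert c.total_genes == 6
        assert c.unique_genes == 5
        assert c.duplicated_in_IR == 1

    def test_census_invariant_under_rotation(self, focal_structured):
        rg, qmap, _ = focal_structured
        rot = rg.rotate(40_000)
        rg2, qmap2 = detect_inverted_repeat(rot)
        c1, c2 = gene_census(rg, qmap), gene_census(rg2, qmap2)
        assert c1.unique_genes == c2.unique_genes
        assert c1.by_class == c2.by_class


class TestIntronInventory:
    def test_seventeen_intron_genes(self, focal_structured):
        rg, qmap, _ = focal_structured
        inv = intron_inventory(rg, qmap)
        assert len(inv) == 17

    def test_trnk_intron_longest_and_hosts_matk(self, focal_structured):
        rg, qmap, _ = focal_structured
        inv = {r.gene: r for r in intron_inventory(rg, qmap)}
        trnk = inv["trnK-UUU"]
        assert trnk.intron_lengths == (2497,)
        assert trnk.nested_genes == ("matK",)
        assert max(max(r.intron_lengths) for r in inv.values()) == 2497
        n = len(rg)
        matk = next(f for f in rg.features if f.name == "matK")
        assert matk.length(n) == 1491

    def test_rps12_trans_spliced_flagged(self, focal_structured):
        rg, qmap, _ = focal_structured
        inv = {r.gene: r for r in intron_inventory(rg, qmap)}
        assert inv["rps12"].trans_spliced
        assert inv["rps12"].intron_lengths == (536,)

    def test_single_exon_genes_absent(self, focal_structured):
        rg, qmap, _ = focal_structured
        inv = {r.gene for r in intron_inventory(rg, qmap)}
        assert "rbcL" not in inv and "psbA" not in inv
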