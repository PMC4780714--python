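"""In-silico PCR and rpl2 intron-loss calls."""

import numpy as np
import pytest

from plastomekit.intron_survey import (RPL2_FORWARD, RPL2_REVERSE, Primer,
                                       classify_by_amplicon,
                                       exon_junction_compare, in_silico_pcr,
                                       intron_presence_from_annotation)
from plastomekit.plastome_io import (AnnotatedPlastome, CircularInterval,
                                     Feature, PlastomeError,
                                     reverse_complement)

FWD = Primer("F", RPL2_FORWARD)
REV = Primer("R", RPL2_REVERSE)


def _template(insert_len: int, seed: int = 5, intron: int = 0) -> str:
    """100 bp + fwd site + insert (optionally with an intron inside) + rev + 100 bp."""
    rng = np.random.default_rng(seed)
    mid = "".join(rng.choice(list("ACGT"), insert_len + intron))
    flank1 = "".join(rng.choice(list("ACGT"), 100))
    flank2 = "".join(rng.choice(list("ACGT"), 100))
    return flank1 + FWD.sequence + mid + reverse_complement(REV.sequence) + flank2


class TestInSilicoPCR:
    def test_constructed_amplicon_arithmetic(self):
        t = _template(700)
        prods = in_silico_pcr(t, FWD, REV)
        assert len(prods) == 1
        assert prods[0].length_bp == 20 + 700 + 20

    def test_missing_reverse_site_gives_no_product(self):
        rng = np.random.default_rng(1)
        t = "".join(rng.choice(list("ACGT"), 100)) + FWD.sequence \
            + "".join(rng.choice(list("ACGT"), 500))
        assert in_silico_pcr(t, FWD, REV) == []

    @pytest.mark.parametrize("intron_len", [500, 575, 650, 660, 725, 800])
    def test_paired_templates_differ_by_exactly_intron_length(self, intron_len):
        without = _template(710, seed=intron_len)
        with_intron = _template(710, seed=intron_len, intron=intron_len)
        a = in_silico_pcr(without, FWD, REV)[0].length_bp
        b = in_silico_pcr(with_intron, FWD, REV)[0].length_bp
        assert b - a == intron_len
        assert classify_by_amplicon(a) == "absent"
        assert classify_by_amplicon(b) == "present"

    def test_primer_on_minus_strand_found(self):
        t = reverse_complement(_template(700))
        prods = in_silico_pcr(t, FWD, REV)
        assert prods and prods[0].length_bp == 740

    def test_mismatch_tolerance_and_exact_three_prime(self):
        t = list(_template(700))
        t[100 + 2] = "A" if t[102] != "A" else "C"     # 5' mismatch tolerated
        prods = in_silico_pcr("".join(t), FWD, REV, max_mismatch=2)
        assert prods
        t[100 + 19] = "A" if t[119] != "A" else "C"    # 3'-terminal mismatch kills
        assert in_silico_pcr("".join(t), FWD, REV, max_mismatch=2) == []


class TestClassification:
    @pytest.mark.parametrize("length,expected", [
        (750, "absent"), (1400, "present"), (1050, "indeterminate"),
        (900, "absent"), (901, "indeterminate"), (1120, "present"),
    ])
    def test_bands(self, length, expected):
        assert classify_by_amplicon(length) == expected


class TestAnnotationCall:
    def test_focal_genome_rpl2_absent(self, focal_structured):
        rg, _, _ = focal_structured
        assert intron_presence_from_annotation(rg, "rpl2").status == "absent"

    def test_two_exon_gene_present(self):
        g = AnnotatedPlastome("x", "A" * 2000, features=[
            Feature("rpl2", "CDS", "+", [CircularInterval(100, 400),
                                         CircularInterval(1000, 1400)])])
        assert intron_presence_from_annotation(g, "rpl2").status == "present"

    def test_disagreeing_ir_copies_indeterminate(self):
        g = AnnotatedPlastome("x", "A" * 3000, features=[
            Feature("rpl2", "CDS", "+", [CircularInterval(100, 400),
                                         CircularInterval(800, 1100)]),
            Feature("rpl2", "CDS", "-", [CircularInterval(2000, 2600)])])
        assert intron_presence_from_annotation(g, "rpl2").status == "indeterminate"

    def test_missing_gene_errors(self, focal_structured):
        rg, _, _ = focal_structured
        with pytest.raises(PlastomeError):
            intron_presence_from_annotation(rg, "nosuchgene")


class TestExonJunction:
    def _make_alignment(self, n_absent=4, n_present=1, intron="GTAAGT" * 20):
        exon1, exon2 = "ATGGCTAAGCTT", "GGATCCTTAGCA"
        ref = exon1 + intron + exon2
        aln = {"ref": ref}
        for i in range(n_present):
            aln[f"with{i}"] = ref
        for i in range(n_absent):
            aln[f"without{i}"] = exon1 + "-" * len(intron) + exon2
        return aln, (len(exon1), len(exon1) + len(intron))

    def test_planted_deletion_called_absent(self):
        aln, iv = self._make_alignment(n_absent=4, n_present=1)
        calls = {c.species: c.status
                 for c in exon_junction_compare(aln, "ref", iv)}
        assert all(calls[f"without{i}"] == "absent" for i in range(4))
        assert calls["with0"] == "present" and calls["ref"] == "present"

    def test_all_identical_all_present(self):
        aln, iv = self._make_alignment(n_absent=0, n_present=3)
        calls = exon_junction_compare(aln, "ref", iv)
        assert all(c.status == "present" for c in calls)

    def test_half_filled_follows_ge_50_rule_flagged(self):
        aln, iv = self._make_alignment(n_absent=0, n_present=0, intron="GT" * 30)
        half = aln["ref"][:iv[0]] + "-" * 30 + aln["ref"][iv[0] + 30:]
        aln["half"] = half
        call = next(c for c in exon_junction_compare(aln, "ref", iv)
                    if c.species == "half")
        assert call.status == "present"
        assert "borderline" in call.detail

    def test_reference_without_intron_errors(self):
        aln = {"ref": "ACGTACGT", "a": "ACGTACGT", "b": "ACGTACGT"}
        with pytest.raises(PlastomeError):
            exon_junction_compare(aln, "ref", (4, 4))

    def test_evolved_set_calls_match_planted_loss(self, evolved_set):
        root, truth, genomes = evolved_set
        for name, g in genomes.items():
            call = intron_presence_from_annotation(g, "rpl2")
            expected = "absent" if name in ("LagA", "LagB") else "present"
            assert call.status == expected, name

    def test_annotation_and_pcr_agree_on_synthetic(self, evolved_set):
        from plastomekit.intron_survey import survey_genomes
        _, _, genomes = evolved_set
        for row in survey_genomes(genomes):
            if row["pcr_call"] != "indeterminate":
                assert row["pcr_call"] == row["annotation_call"], row
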