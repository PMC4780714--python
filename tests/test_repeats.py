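"""SSR / tandem / dispersed repeat scanners, validated against brute force."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plastomekit.repeats import (RepeatSearchParams, SSRThresholds, TandemParams,
                                 analysis_sequence, find_dispersed_repeats,
                                 find_ssrs, find_tandem_repeats,
                                 merge_overlapping)
from plastomekit.structure import detect_inverted_repeat
from plastomekit.synthetic_data import PlastomeSpec, simulate_plastome

from .oracles import dispersed_to_set, oracle_dispersed, oracle_ssrs


def _ssr_set(hits):
    return {(h.motif, int(h.copies), int(h.start), int(h.end)) for h in hits}


class TestAnalysisSequence:
    def test_one_ir_copy_removed(self, focal_structured):
        rg, qmap, _ = focal_structured
        seq, rmap = analysis_sequence(rg, qmap)
        assert len(seq) == len(rg) - qmap.ir_length

    def test_no_ir_genome_returns_identity(self):
        from plastomekit.plastome_io import AnnotatedPlastome
        g = AnnotatedPlastome("r", "ACGT" * 2500)
        seq, rmap = analysis_sequence(g, None)
        assert seq == g.sequence

    def test_regions_round_trip(self, focal_structured):
        rg, qmap, _ = focal_structured
        seq, rmap = analysis_sequence(rg, qmap)
        rng = np.random.default_rng(3)
        n = len(rg)
        for pos in rng.integers(0, len(seq), size=200):
            reg = rmap.region_of(int(pos))
            assert reg in ("LSC", "IR", "SSC")
            full = qmap.region_of(rmap.to_genomic(int(pos)))
            assert full.replace("_B", "") == reg


class TestSSRs:
    @pytest.mark.parametrize("seq,expected", [
        ("GAAAAAAAAC", {("A", 8, 1, 9)}),          # 8xA passes the threshold
        ("GAAAAAAAC", set()),                      # 7xA does not
        ("ATATATAT", {("AT", 4, 0, 8)}),
        ("ATATAT", set()),
        ("AAGAAGAAG", {("AAG", 3, 0, 9)}),
    ])
    def test_threshold_boundaries(self, seq, expected):
        assert _ssr_set(find_ssrs(seq)) == expected

    def test_poly_a_not_double_reported_as_dinucleotide(self):
        hits = find_ssrs("G" + "A" * 12 + "C")
        assert len(hits) == 1 and hits[0].motif == "A"

    @pytest.mark.parametrize("seed", range(11, 16))
    def test_matches_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 10_000, p=[.35, .15, .15, .35]))
        assert _ssr_set(find_ssrs(seq)) == oracle_ssrs(seq)

    def test_matches_oracle_on_exhaustive_short_binary_strings(self):
        thr = SSRThresholds(mono=3, di=2, tri=2, tetra=2, penta=2)
        for L in range(1, 13):
            for bits in itertools.product("AC", repeat=L):
                seq = "".join(bits)
                got = _ssr_set(find_ssrs(seq, thr))
                assert got == oracle_ssrs(seq, (3, 2, 2, 2, 2)), seq

    def test_no_hit_contained_in_same_motif_hit(self, focal_structured):
        rg, qmap, _ = focal_structured
        seq, rmap = analysis_sequence(rg, qmap)
        hits = find_ssrs(seq)
        by_motif = {}
        for h in hits:
            by_motif.setdefault(h.motif, []).append(h)
        for group in by_motif.values():
            for a in group:
                for b in group:
                    if a is not b:
                        assert not (b.start <= a.start and a.end <= b.end)

    @given(st.integers(2, 8))
    def test_lowering_thresholds_never_loses_hits(self, mono):
        seq = "GAAAAAAAACCTCTCTCTCTGGATATATAT"
        hi = find_ssrs(seq, SSRThresholds(mono=mono, di=4, tri=3, tetra=3, penta=3))
        lo = find_ssrs(seq, SSRThresholds(mono=2, di=2, tri=2, tetra=2, penta=2))
        assert _ssr_set(hi) <= _ssr_set(lo)

    def test_planted_ssrs_recovered(self, focal_structured):
        rg, qmap, truth = focal_structured
        seq, rmap = analysis_sequence(rg, qmap)
        hits = find_ssrs(seq, features=rg.features, region_map=rmap)
        for motif, copies, s, e, region in truth.ssrs:
            match = [h for h in hits if h.motif == motif
                     and h.start <= s and h.end >= e]
            assert match, f"planted SSR {motif}x{copies} at {s} not recovered"
            assert match[0].region == region


class TestTandem:
    def test_exact_triple_copy_scores_and_reports(self):
        rng = np.random.default_rng(0)
        unit = "".join(rng.choice(list("ACGT"), 25))
        seq = "".join(rng.choice(list("ACGT"), 300)) + unit * 3 \
            + "".join(rng.choice(list("ACGT"), 300))
        hits = find_tandem_repeats(seq)
        assert len(hits) == 1
        h = hits[0]
        assert h.period == 25
        assert h.score >= 2 * 50          # 50 scored positions x +2
        assert h.start <= 300 and h.end >= 300 + 75

    def test_two_copies_with_four_mismatches_rejected(self):
        # 20-mer x2 with 4 mismatches: score 16*2 - 4*7 = 4 < 50
        rng = np.random.default_rng(5)
        unit = "".join(rng.choice(list("ACGT"), 20))
        copy2 = list(unit)
        for pos in (2, 7, 12, 17):
            copy2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy2[pos]]
        seq = "".join(rng.choice(list("ACGT"), 200)) + unit + "".join(copy2) \
            + "".join(rng.choice(list("ACGT"), 200))
        assert find_tandem_repeats(seq) == []

    def test_planted_arrays_recovered_and_controls_clean(self, focal_structured):
        rg, qmap, truth = focal_structured
        seq, rmap = analysis_sequence(rg, qmap)
        hits = find_tandem_repeats(seq, region_map=rmap)
        for unit, copies, s, e, period, region in truth.tandems:
            assert any(h.start <= s and h.end >= e for h in hits), \
                f"planted tandem p={period} not recovered"
        # random controls: spurious hit rate below 1 %
        spurious = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ctrl = "".join(rng.choice(list("ACGT"), 2_000))
            if find_tandem_repeats(ctrl):
                spurious += 1
        assert spurious <= 1


class TestDispersed:
    def test_planted_exact_forward_copy(self):
        rng = np.random.default_rng(2)
        bg = "".join(rng.choice(list("ACGT"), 3_000))
        chunk = bg[100:140]
        seq = bg[:1_500] + chunk + bg[1_500:]
        hits = find_dispersed_repeats(seq, RepeatSearchParams(classes=("forward",)))
        # maximal windows absorb the mismatch budget into the random flanks,
        # so the planted exact copy appears inside length >= 40 hits
        assert any(h.start1 <= 100 and h.end1 >= 140
                   and h.start2 <= 1500 and h.end2 >= 1540 for h in hits)

    def test_planted_palindromic_copy(self):
        from plastomekit.plastome_io import reverse_complement
        rng = np.random.default_rng(4)
        bg = "".join(rng.choice(list("ACGT"), 3_000))
        chunk = reverse_complement(bg[200:240])
        seq = bg[:2_000] + chunk + bg[2_000:]
        hits = find_dispersed_repeats(seq, RepeatSearchParams(classes=("palindromic",)))
        assert any(h.length >= 40 and h.start1 <= 200 and h.end1 >= 240 for h in hits)

    def test_sequence_shorter_than_min_len_returns_empty(self):
        assert find_dispersed_repeats("ACGTACGT") == []

    @pytest.mark.parametrize("seed", range(1, 5))
    def test_matches_quadratic_oracle_with_planted_repeats(self, seed):
        from plastomekit.plastome_io import reverse_complement
        rng = np.random.default_rng(seed)
        bg = list("".join(rng.choice(list("ACGT"), 500)))
        # plant one near-exact copy in a random orientation
        src = "".join(bg[50:85])
        dst = int(rng.integers(300, 500))
        cls = ["forward", "reverse", "complement", "palindromic"][seed % 4]
        comp = str.maketrans("ACGT", "TGCA")
        planted = {"forward": src, "reverse": src[::-1],
                   "complement": src.translate(comp),
                   "palindromic": reverse_complement(src)}[cls]
        planted = list(planted)
        if seed % 2:
            planted[5] = "A" if planted[5] != "A" else "C"   # one mismatch
        bg[dst:dst + 35] = planted
        seq = "".join(bg)
        got = dispersed_to_set(find_dispersed_repeats(seq))
        want = oracle_dispersed(seq)
        assert got == want

    def test_matches_oracle_on_binary_alphabet(self):
        rng = np.random.default_rng(99)
        for _ in range(3):
            seq = "".join(rng.choice(list("AC"), 150))
            got = dispersed_to_set(
                find_dispersed_repeats(seq, RepeatSearchParams(min_len=12, max_hamming=2)))
            want = oracle_dispersed(seq, min_len=12, h=2)
            assert got == want


class TestMerge:
    def _mk(self, cls, s1, e1, s2, e2):
        from plastomekit.repeats import RepeatHit
        return RepeatHit(cls, s1, e1, s2, e2, e1 - s1, 0)

    def test_overlapping_hits_fuse(self):
        a = self._mk("forward", 10, 50, 200, 240)
        b = self._mk("forward", 12, 52, 202, 242)
        merged = merge_overlapping([a, b])
        assert len(merged) == 1
        m = merged[0]
        assert (m.start1, m.end1, m.start2, m.end2) == (10, 52, 200, 242)

    def test_disjoint_hits_unchanged(self):
        a = self._mk("forward", 10, 50, 200, 240)
        b = self._mk("forward", 300, 340, 500, 540)
        assert len(merge_overlapping([a, b])) == 2

    def test_idempotent(self):
        hits = [self._mk("forward", 10, 50, 200, 240),
                self._mk("forward", 30, 70, 220, 260),
                self._mk("palindromic", 5, 40, 400, 435)]
        once = merge_overlapping(hits)
        assert merge_overlapping(once) == once
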