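"""Shared-region extraction, alignment, site statistics, PIC% and RI."""

import numpy as np
import pytest

from plastomekit.parsimony import PhyloTree, mp_search
from plastomekit.plastome_io import AnnotatedPlastome, PlastomeError
from plastomekit.variability import (RegionAlignment, WindowSpec, align_region,
                                     extract_shared_regions, pic_percent,
                                     rank_regions, retention_index,
                                     score_region, site_classes,
                                     sliding_windows)


class TestExtractSharedRegions:
    def _pair(self):
        from plastomekit.synthetic_data import (GeneTemplate, PlastomeSpec,
                                                simulate_plastome)
        tmpl = [GeneTemplate("A", "CDS", "LSC", "+", (400,)),
                GeneTemplate("B", "CDS", "LSC", "+", (300,)),
                GeneTemplate("C", "CDS", "LSC", "+", (500,))]
        out = {}
        for seed in (1, 2):
            spec = PlastomeSpec(lsc_len=20_000, ssc_len=5_000, ir_len=11_000,
                                gene_templates=tmpl, planted_ssrs=[],
                                planted_tandems=[], planted_dispersed=[],
                                seed=seed)
            g, _ = simulate_plastome(spec)
            out[f"sp{seed}"] = g
        return out

    def test_shared_cds_and_igs_extracted(self):
        regions = extract_shared_regions(self._pair(), min_len=200)
        names = {(r.name, r.region_class) for r in regions}
        assert ("A", "CDS") in names and ("B", "CDS") in names \
            and ("C", "CDS") in names
        igs = {n for n, c in names if c == "IGS"}
        assert "A-B" in igs and "B-C" in igs

    def test_short_regions_dropped(self):
        genomes = self._pair()
        regions = extract_shared_regions(genomes, min_len=450)
        assert {r.name for r in regions if r.region_class == "CDS"} == {"C"}

    def test_no_shared_genes_errors(self):
        g1 = AnnotatedPlastome("a", "ACGT" * 100)
        g2 = AnnotatedPlastome("b", "ACGT" * 100)
        with pytest.raises(PlastomeError):
            extract_shared_regions({"a": g1, "b": g2})

    def test_evolved_set_regions_shared_across_all(self, evolved_set):
        _, _, genomes = evolved_set
        regions = extract_shared_regions(genomes)
        assert len(regions) > 50
        for r in regions:
            assert set(r.sequences) == set(genomes)
        # IR-duplicated genes appear once
        names = [r.name for r in regions]
        assert len(names) == len(set(names))


class TestAlignment:
    def test_identical_sequences_gapless(self):
        aln = align_region({"a": "ACGTACGTAA", "b": "ACGTACGTAA", "c": "ACGTACGTAA"})
        assert aln.aligned_length == 10
        assert all("-" not in s for s in aln.sequences.values())

    def test_single_deletion_gives_one_gap_column(self):
        aln = align_region({"a": "ACGTACGT", "b": "ACGACGT"})
        rows = aln.sequences
        assert aln.aligned_length == 8
        assert rows["a"] == "ACGTACGT"
        assert rows["b"].count("-") == 1
        assert rows["b"].replace("-", "") == "ACGACGT"

    def test_external_alignment_passthrough(self):
        rows = {"a": "AC-GT", "b": "ACTGT"}
        aln = align_region(rows)
        assert aln.source == "external_file"
        assert aln.sequences == rows

    def test_three_way_progressive_alignment_restores_deletion(self):
        base = "ACGTTGCAACGGTACGATTACGGATCGA" * 4
        b = base[:40] + base[43:]      # 3 bp deletion
        aln = align_region({"a": base, "b": b, "c": base})
        assert aln.aligned_length == len(base)
        assert aln.sequences["b"].count("-") == 3


class TestSiteClasses:
    def test_definitions(self):
        got = site_classes({"a": "AACA", "b": "AACA", "c": "ACCA", "d": "ACGA"})
        conserved, variable, informative, singleton = got
        assert (conserved, variable, informative, singleton) == (2, 2, 1, 1)

    def test_gap_and_missing_columns(self):
        aln = {"a": "A--", "b": "AN-", "c": "AC-", "d": "AC-"}
        # col0 conserved; col1: one C-pair + missing -> C,C among called = conserved
        # col2 entirely missing -> unscored
        assert site_classes(aln) == (2, 0, 0, 0)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_matches_per_column_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"s{i}" for i in range(7)]
        aln = {t: "".join(rng.choice(list("ACGT-N"), 500,
                                     p=[.23, .23, .23, .23, .05, .03]))
               for t in taxa}
        cons = var = inf = sing = 0
        for j in range(500):
            col = [aln[t][j] for t in taxa]
            counts = {}
            for ch in col:
                if ch in "ACGT":
                    counts[ch] = counts.get(ch, 0) + 1
            if not counts:
                continue
            if len(counts) == 1:
                cons += 1
            else:
                var += 1
                if sum(1 for v in counts.values() if v >= 2) >= 2:
                    inf += 1
                else:
                    sing += 1
        assert site_classes(aln) == (cons, var, inf, sing)


class TestPicPercent:
    @pytest.mark.parametrize("inf,length,expected", [
        (77, 1101, 6.99), (98, 1593, 6.15), (0, 500, 0.0),
    ])
    def test_reported_to_two_decimals(self, inf, length, expected):
        assert pic_percent(inf, length) == expected

    def test_zero_length_errors(self):
        with pytest.raises(PlastomeError):
            pic_percent(1, 0)


class TestRetentionIndex:
    def test_hand_enumerated_five_taxon_matrix(self):
        # columns: AACCC / ACACA / AAACC on ((t1,t2),(t3,(t4,t5)))
        # per column (m, g, S): (1,2,1), (1,2,2), (1,2,1)
        # RI = (6 - 4) / (6 - 3) = 2/3
        aln = {"t1": "AAA", "t2": "ACA", "t3": "CAA", "t4": "CCC", "t5": "CAC"}
        tree = PhyloTree(("t1", "t2", "t3", "t4", "t5"), (1, (2, (3, 4))))
        ri, defined = retention_index(tree, aln)
        assert defined and ri == pytest.approx(2 / 3)

    def test_homoplasy_free_data_gives_one(self):
        # four informative columns all consistent with the ab|cd split plus
        # one singleton: no homoplasy on the MP tree
        aln = {"a": "AAAAA", "b": "AAAAC", "c": "CCGGA", "d": "CCGGA"}
        res = mp_search(aln)
        ri, defined = retention_index(res.best_trees[0], aln)
        assert defined and ri == pytest.approx(1.0)

    def test_worst_case_zero(self):
        # singleton-only variation: g == m for every column -> undefined
        aln = {"a": "AC", "b": "AA", "c": "CA", "d": "AA"}
        tree = PhyloTree(("a", "b", "c", "d"), (1, (2, 3)))
        ri, defined = retention_index(tree, aln)
        assert not defined and ri == 1.0

    def test_invariant_under_taxon_and_column_permutation(self):
        rng = np.random.default_rng(5)
        taxa = tuple(f"s{i}" for i in range(6))
        aln = {t: "".join(rng.choice(list("ACGT"), 60, p=[.4, .2, .2, .2]))
               for t in taxa}
        tree = mp_search(aln).best_trees[0]
        ri1, _ = retention_index(tree, aln)
        perm = rng.permutation(60)
        aln2 = {t: "".join(aln[t][i] for i in perm) for t in reversed(taxa)}
        ri2, _ = retention_index(tree, aln2)
        assert ri1 == pytest.approx(ri2)

    def test_fitch_bounds_hold(self):
        from plastomekit.variability import _column_bounds
        from plastomekit.parsimony import fitch_column_steps
        rng = np.random.default_rng(9)
        taxa = tuple(f"s{i}" for i in range(7))
        aln = {t: "".join(rng.choice(list("ACGT"), 80)) for t in taxa}
        tree = mp_search(aln, method="tbr", seed=0).best_trees[0]
        m, g = _column_bounds(aln)
        s = fitch_column_steps(tree, aln)
        assert (m <= s).all() and (s <= g).all()


class TestWindows:
    def test_threshold_and_arithmetic(self):
        assert sliding_windows(1400) == []
        assert sliding_windows(2300) == [(0, 1000), (500, 1500),
                                         (1000, 2000), (1500, 2300)]

    def test_ycf1_scale_has_fourteen_windows(self):
        assert len(sliding_windows(7356)) == 14

    def test_invalid_step_errors(self):
        with pytest.raises(PlastomeError):
            sliding_windows(3000, WindowSpec(window=100, step=500))

    def test_divergence_hotspot_window_identified(self):
        # 7-taxon 7kb alignment, divergence concentrated at 5-6 kb
        rng = np.random.default_rng(17)
        base = "".join(rng.choice(list("ACGT"), 7000))
        taxa = {}
        for i in range(7):
            row = list(base)
            # background: sparse variation; hotspot: dense
            for j in rng.choice(7000, 30, replace=False):
                row[j] = "ACGT"[(("ACGT".index(row[j])) + 1 + i % 3) % 4]
            if i % 2 == 0:
                for j in range(5000, 6000, 7):
                    row[j] = "ACGT"[("ACGT".index(row[j]) + 1) % 4]
            taxa[f"s{i}"] = "".join(row)
        scores = []
        for (ws, we) in sliding_windows(7000):
            sub = {t: s[ws:we] for t, s in taxa.items()}
            _, _, inf, _ = site_classes(sub)
            scores.append((pic_percent(inf, we - ws), ws))
        best = max(scores)
        assert best[1] in (5000, 5500)


class TestRanking:
    def _stats(self, name, cls, pic, alen):
        from plastomekit.variability import VariabilityStats
        return VariabilityStats(name, cls, alen, alen, 0, 0, 0, 0, pic, 1.0)

    def test_sorted_by_pic_with_tie_rules(self):
        rows = [self._stats("a", "CDS", 5.0, 100),
                self._stats("b", "CDS", 7.0, 100),
                self._stats("c", "CDS", 5.0, 300),
                self._stats("d", "IGS", 9.0, 50)]
        coding, noncoding = rank_regions(rows, k=10)
        assert [s.region_name for s in coding] == ["b", "c", "a"]
        assert [s.region_name for s in noncoding] == ["d"]

    def test_k_larger_than_available_returns_all(self):
        rows = [self._stats("a", "CDS", 5.0, 100)]
        coding, _ = rank_regions(rows, k=10)
        assert len(coding) == 1

    def test_planted_divergence_gradient_ranking(self):
        rng = np.random.default_rng(31)
        stats = []
        rates = {"r1": 0.005, "r2": 0.02, "r3": 0.08}
        for name, rate in rates.items():
            base = "".join(rng.choice(list("ACGT"), 800))
            rows = {f"s{i}": list(base) for i in range(5)}
            # shared derived states in (s0, s1) -> informative columns whose
            # count tracks the planted divergence rate exactly
            for j in rng.choice(800, int(800 * rate), replace=False):
                new = "ACGT"[("ACGT".index(base[j]) + 1) % 4]
                rows["s0"][j] = rows["s1"][j] = new
            aln = {t: "".join(r) for t, r in rows.items()}
            ra = RegionAlignment(name, "CDS", aln, 800)
            stats.append(score_region(ra, 800))
        coding, _ = rank_regions(stats, k=3)
        assert [s.region_name for s in coding] == ["r3", "r2", "r1"]
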