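"""Hairpin detection, tandem-repeat decomposition and motif scanning."""

import numpy as np
import pytest

from mitopair.divergence import AlignedPair, p_distance
from mitopair.genomes import Feature, FeatureTable, GenomeRecord, reverse_complement
from mitopair.noncoding import (
    find_hairpins,
    find_tandem_repeats,
    motif_scan,
    scan_gene_upstream_hairpins,
    unit_distance_matrix,
)
from mitopair.simulate import random_dna

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
COMP = (39.3, 12.0, 27.2, 21.4)


def exhaustive_hairpin_oracle(seq, min_stem=5, loop_range=(3, 30)):
    """Test every (arm start, stem, loop) triple; keep outward-maximal hits."""
    seq = seq.upper()
    n = len(seq)
    out = set()
    for s in range(n):
        for k in range(min_stem, n):
            for loop in range(loop_range[0], loop_range[1] + 1):
                e = s + 2 * k + loop
                if e > n:
                    break
                arm5, arm3 = seq[s:s + k], seq[s + k + loop:e]
                if all((arm5[i], arm3[k - 1 - i]) in WC for i in range(k)):
                    if s - 1 >= 0 and e < n and (seq[s - 1], seq[e]) in WC:
                        continue  # extendable outward: not maximal
                    out.add((s + 1, k, loop))
    return out


class TestFindHairpins:
    def test_perfect_palindrome(self):
        hits = find_hairpins("GCGCGAAAACGCGC", min_stem=5, loop_range=(3, 8))
        assert [(h.start, h.stem_len, h.loop_len) for h in hits] == [(1, 5, 4)]
        h = hits[0]
        assert h.arm5 == "GCGCG" and h.arm3 == "CGCGC" and h.span == 14

    def test_arms_are_reverse_complements(self):
        for h in find_hairpins("TTACCGGTTAACCGGT" * 2):
            assert reverse_complement(h.arm5) == h.arm3

    def test_homopolymer_cannot_pair(self):
        assert find_hairpins("AAAAAAAAAA") == []

    def test_min_stem_parameter_validated(self):
        with pytest.raises(ValueError):
            find_hairpins("ACGT", min_stem=1)

    def test_gu_pairing_opt_in(self):
        # stem needs G-T pairs: GTGTG ... CGCGC won't pair under WC
        seq = "GGGGG" + "AAAA" + "TTTTT"
        wc = find_hairpins(seq, min_stem=5, loop_range=(3, 6))
        gu = find_hairpins(seq, min_stem=5, loop_range=(3, 6), allow_gu=True)
        assert wc == []
        assert any((h.start, h.stem_len, h.loop_len) == (1, 5, 4) for h in gu)

    def test_matches_exhaustive_oracle_on_random_sequences(self, rng):
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=160))
            got = {(h.start, h.stem_len, h.loop_len) for h in find_hairpins(seq)}
            assert got == exhaustive_hairpin_oracle(seq)

    def test_results_sorted_by_position(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        hits = find_hairpins(seq, min_stem=4)
        assert [h.start for h in hits] == sorted(h.start for h in hits)


class TestUpstreamHairpinScan:
    def _genome(self, rng):
        """gene X preceded by a hairpin-bearing UR, gene Y preceded by a tRNA."""
        stem, loop = "GCCGAGC", "TTTAT"
        hairpin = stem + loop + reverse_complement(stem)
        gene_x = "ATG" + "GCT" * 20 + "TAA"
        gene_y = "ATG" + "CTT" * 20 + "TAA"
        trna = random_dna(rng, 65, COMP)
        ur1 = random_dna(rng, 20, COMP) + hairpin + random_dna(rng, 6, COMP)
        parts = [gene_x, random_dna(rng, 30, COMP), trna, gene_y, ur1]
        seq = "".join(parts)
        # circular: ur1 sits at the end, upstream of gene X at position 1
        feats = []
        pos = 0
        for name, ftype, s in [
            ("geneX", "CDS", gene_x), (None, None, parts[1]),
            ("trnQ", "tRNA", trna), ("geneY", "CDS", gene_y),
        ]:
            if name:
                feats.append(Feature(ftype=ftype, name=name, start=pos + 1,
                                     stop=pos + len(s),
                                     **({"start_codon": "ATG", "stop_codon": "TAA"}
                                        if ftype == "CDS" else {})))
            pos += len(s)
        genome = GenomeRecord("toy", len(seq), seq)
        ft = FeatureTable("toy", len(seq), feats)
        hairpin_abs_start = len(seq) - len(ur1) + 21
        return genome, ft, hairpin_abs_start

    def test_planted_hairpin_found_and_trna_preceded_gene_skipped(self, rng):
        genome, ft, hp_start = self._genome(rng)
        res = scan_gene_upstream_hairpins(genome, ft, window=60, min_stem=5)
        assert "geneY" not in res  # tRNA directly upstream
        xs = res["geneX"]
        # accidental pairing of flanking bases may extend the planted stem
        assert any(abs(g_start - hp_start) <= 2 for _, g_start, _ in xs)

    def test_hairpin_containing_start_codon_flagged(self):
        stem = "GGCGCAG"
        # hairpin arms straddle the ATG: plant the 3' arm just after the start
        gene = "ATG" + reverse_complement(stem) + "GCTGCT" * 5 + "TAA"
        ur = "TTATTAAT" + stem + "TT"  # loop continues across the gene start
        lead = "ATGCCTCCTCCTTAA"
        seq = lead + ur + gene
        feats = [
            Feature(ftype="CDS", name="lead", start=1, stop=len(lead),
                    start_codon="ATG", stop_codon="TAA"),
            Feature(ftype="CDS", name="geneZ", start=len(lead) + len(ur) + 1,
                    stop=len(seq), start_codon="ATG", stop_codon="TAA"),
        ]
        genome = GenomeRecord("t", len(seq), seq)
        ft = FeatureTable("t", len(seq), feats)
        res = scan_gene_upstream_hairpins(genome, ft, window=40, min_stem=5)
        assert any(contains for _, _, contains in res["geneZ"])

    def test_equals_independent_scan_of_the_region(self, rng):
        genome, ft, _ = self._genome(rng)
        res = scan_gene_upstream_hairpins(genome, ft, window=60, min_stem=4)
        gene_x = ft.get("geneX")
        n = genome.length
        # compositional oracle: scan the same unwrapped window directly
        upstream_gap = n - ft.get("geneY").stop  # the trailing UR
        lo = n + 1 - min(60, upstream_gap)
        region = genome.sequence[lo - 1:] + genome.sequence[:3 + 2]
        direct = find_hairpins(region, min_stem=4)
        assert [(h.stem_len, h.loop_len) for h, _, _ in res["geneX"]] == [
            (h.stem_len, h.loop_len) for h in direct]


class TestTandemRepeats:
    def test_exact_dimer(self, rng):
        unit = random_dna(rng, 500, COMP)
        dec = find_tandem_repeats(unit + unit, min_unit=100, B=20, seed=1)
        assert [(u.start, u.stop, u.truncated) for u in dec.units] == [
            (1, 500, False), (501, 1000, False)]
        assert dec.pd_matrix[0, 1] == 0.0

    def test_diverged_dimer_pd_within_binomial_error(self, rng):
        """Two units at the published control-region regime (~0.4%): the
        decomposition recovers both units and their p-distance."""
        unit = random_dna(rng, 2150, COMP)
        copy = list(unit)
        sites = rng.choice(2150, size=9, replace=False)  # 9/2150 = 0.42%
        for s in sites:
            copy[s] = rng.choice([b for b in "ACGT" if b != copy[s]])
        seq = unit + "".join(copy)
        dec = find_tandem_repeats(seq, min_unit=500, B=100, seed=2)
        assert dec.n_units == 2
        planted = 9 / 2150
        se = np.sqrt(planted * (1 - planted) / 2150)
        assert dec.pd_matrix[0, 1] == pytest.approx(planted, abs=3 * se)

    def test_truncated_trailing_unit(self, rng):
        unit = random_dna(rng, 400, COMP)
        seq = unit * 3 + unit[:17] + random_dna(rng, 50, COMP)
        dec = find_tandem_repeats(seq, min_unit=100, B=20, seed=3)
        assert dec.n_units == 4
        last = dec.units[-1]
        assert last.truncated and abs(last.length - 17) <= 3

    def test_units_are_disjoint_ordered_and_contained(self, rng):
        unit = random_dna(rng, 300, COMP)
        seq = random_dna(rng, 70, COMP) + unit * 3 + random_dna(rng, 70, COMP)
        dec = find_tandem_repeats(seq, min_unit=100, B=20, seed=4)
        prev_stop = 0
        for u in dec.units:
            assert u.start > prev_stop
            assert 1 <= u.start <= u.stop <= len(seq)
            prev_stop = u.stop

    def test_too_short_sequence_gives_empty_decomposition(self):
        dec = find_tandem_repeats("ACGTACGT", min_unit=50)
        assert dec.n_units == 0


class TestUnitDistanceMatrix:
    def test_identical_units(self):
        pd_m, se_m = unit_distance_matrix(["ACGTACGT"] * 3, B=20, seed=0)
        assert (pd_m == 0).all() and (se_m == 0).all()

    def test_two_units_reduce_to_scalar_p_distance(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = "".join(rng.choice(list("ACGT"), size=200))
        pd_m, se_m = unit_distance_matrix([a, b], B=200, seed=7)
        est = p_distance(AlignedPair(a, b), B=200, seed=7)
        assert pd_m[0, 1] == est.pD and se_m[0, 1] == est.SE

    def test_planted_divergences_recovered_and_symmetric(self, rng):
        """Mutual divergences like the within-genome (~1%) versus
        between-genome (~35%) repeat distances."""
        base = random_dna(rng, 1000, COMP)

        def mutate(seq, k):
            out = list(seq)
            for s in rng.choice(len(seq), size=k, replace=False):
                out[s] = rng.choice([b for b in "ACGT" if b != out[s]])
            return "".join(out)

        units = [base, mutate(base, 10), mutate(base, 350)]
        pd_m, _ = unit_distance_matrix(units, B=50, seed=1)
        assert np.allclose(pd_m, pd_m.T) and np.all(np.diag(pd_m) == 0)
        assert pd_m[0, 1] == pytest.approx(0.01, abs=0.005)
        assert pd_m[0, 2] == pytest.approx(0.35, abs=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            unit_distance_matrix(["ACGT", "ACGTA"])


class TestMotifScan:
    def test_exact_double_plant(self, rng):
        motif = random_dna(rng, 46, COMP)
        seq = random_dna(rng, 50, COMP) + motif + random_dna(rng, 20, COMP) + motif
        hits = motif_scan(seq, motif)
        assert [h for h in hits] == [(51, 0), (117, 0)]

    def test_mismatched_plant_reports_distance(self, rng):
        motif = random_dna(rng, 30, COMP)
        variant = list(motif)
        variant[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[variant[5]]
        variant[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[variant[20]]
        seq = random_dna(rng, 40, COMP) + "".join(variant)
        hits = motif_scan(seq, motif, max_mismatch=2)
        assert (41, 2) in hits

    def test_matches_sliding_window_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        motif = "".join(rng.choice(list("ACGT"), size=6))
        got = motif_scan(seq, motif, max_mismatch=2)
        expected = []
        for i in range(len(seq) - 6 + 1):
            mm = sum(a != b for a, b in zip(seq[i:i + 6], motif))
            if mm <= 2:
                expected.append((i + 1, mm))
        assert got == expected

    def test_motif_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            motif_scan("ACG", "ACGT")
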