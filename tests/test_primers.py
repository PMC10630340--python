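import itertools

import numpy as np
import pytest

from nestprimer.config import PipelineConfig
from nestprimer.msa import CandidateMsa, CodonMsa, PairwiseStats
from nestprimer.primers import (
    CODE_TO_BASES,
    InnerPair,
    NestedPrimerSet,
    PrimerBlock,
    _CandidateView,
    build_degenerate_primer,
    design_primers_brute,
    design_primers_for_candidate,
    emit_outputs,
    enumerate_inner_pairs,
    find_outer_pairs,
    find_primer_blocks,
    score_infor,
    score_nested_sets,
    score_pcr,
    select_best_per_msa,
    total_score,
)

from oracles import brute_mean_identity, brute_mean_p_distance, enumerate_degeneracy

CFG = PipelineConfig()
STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(rng, n_codons):
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in STOPS:
            codons.append(c)
    return "".join(codons)


def _candidate(rows, ref="reference"):
    cmsa = CodonMsa(rows=rows, ref_taxon=ref)
    return CandidateMsa(
        msa=cmsa,
        left_block_start=0,
        right_block_start=cmsa.n_cols // 3 - 8,
        mean_pairwise_identity_nt=0.8,
    )


def _planted_candidate(rng, mid_codons=120, flank_codons=20, divergence=0.3, n_rows=4):
    """Four perfectly conserved 8-codon blocks with divergent spacers:
    outer_f | flank | inner_f | middle | inner_r | flank | outer_r."""
    blocks = [_random_cds(rng, 8) for _ in range(4)]
    flank1, flank2 = _random_cds(rng, flank_codons), _random_cds(rng, flank_codons)
    middle = _random_cds(rng, mid_codons)
    ref = blocks[0] + flank1 + blocks[1] + middle + blocks[2] + flank2 + blocks[3]
    rows = {"reference": ref}
    for i in range(n_rows - 1):
        def mutate(seg):
            out = list(seg)
            for k in range(len(out)):
                if rng.random() < divergence:
                    out[k] = "ACGT"[int(rng.integers(4))]
            return "".join(out)
        rows[f"t{i}"] = (
            blocks[0] + mutate(flank1) + blocks[1] + mutate(middle)
            + blocks[2] + mutate(flank2) + blocks[3]
        )
    return _candidate(rows)


class TestFindBlocks:
    def test_fully_conserved_window_has_similarity_one_and_singleton_unions(self):
        dna = "ATGAAAGTTCTTATTTGGGCAGAT"   # 8 codons
        cand = _candidate({"reference": dna, "a": dna, "b": dna})
        blocks = find_primer_blocks(cand, CFG)
        eight = [b for b in blocks if b.len_aa == 8]
        assert len(eight) == 1
        block = eight[0]
        assert block.block_similarity == 1.0
        assert all(len(u) == 1 for u in block.nt_unions)
        assert block.degeneracy == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_block_scan_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 30))
        rows = {"reference": _random_cds(rng, n)}
        base = rows["reference"]
        for i in range(3):
            row = list(base)
            for k in range(len(row)):
                if rng.random() < 0.25:
                    row[k] = "ACGT"[int(rng.integers(4))]
            rows[f"t{i}"] = "".join(row)
        cand = _candidate(rows)
        blocks = find_primer_blocks(cand, CFG)
        # oracle: brute-force every window at both lengths
        aa_rows = list(cand.msa.aa_rows().values())
        expected = []
        for length in (7, 8):
            for start in range(n - length + 1):
                window = [r[start:start + length] for r in aa_rows]
                sim = brute_mean_identity(window)
                if sim > 0.5:
                    expected.append((start, length, sim))
        got = [(b.aa_start, b.len_aa, b.block_similarity) for b in blocks]
        assert sorted(got) == sorted(
            [(s, l, pytest.approx(v)) for s, l, v in expected],
            key=lambda x: (x[0], x[1]),
        )

    def test_monotone_in_similarity_threshold(self):
        rng = np.random.default_rng(21)
        cand = _planted_candidate(rng)
        counts = []
        for threshold in (0.3, 0.5, 0.7, 0.9):
            cfg = CFG.replace(block_min_similarity=threshold)
            counts.append(len(find_primer_blocks(cand, cfg)))
        assert counts == sorted(counts, reverse=True)


class TestDegeneratePrimer:
    def test_union_to_iupac_and_degeneracy(self):
        block = PrimerBlock(
            aa_start=0, len_aa=1, block_similarity=1.0,
            nt_unions=[frozenset("AG"), frozenset("C"), frozenset("CT")],
        )
        fwd = build_degenerate_primer(block, "forward")
        assert fwd.iupac == "RCY"
        assert fwd.degeneracy == 4
        rev = build_degenerate_primer(block, "reverse")
        assert rev.iupac == "RGY"   # revcomp of RCY
        assert rev.degeneracy == 4

    def test_empty_union_rejected(self):
        block = PrimerBlock(
            aa_start=0, len_aa=1, block_similarity=1.0,
            nt_unions=[frozenset("A"), frozenset(), frozenset("T")],
        )
        with pytest.raises(ValueError, match="empty base union"):
            build_degenerate_primer(block, "forward")

    @pytest.mark.parametrize("seed", range(10))
    def test_degeneracy_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            unions = [
                frozenset(rng.choice(list("ACGT"), int(rng.integers(1, 4)), replace=False))
                for _ in range(int(rng.integers(3, 10)))
            ]
            deg = 1
            for u in unions:
                deg *= len(u)
            if deg <= 1024:
                break
        block = PrimerBlock(0, 1, 1.0, unions)
        primer = build_degenerate_primer(block, "forward")
        assert primer.degeneracy == deg == enumerate_degeneracy(primer.iupac)
        rev = build_degenerate_primer(block, "reverse")
        assert enumerate_degeneracy(rev.iupac) == deg


class TestInnerPairs:
    def test_two_qualifying_blocks_one_pair(self):
        rng = np.random.default_rng(30)
        dna = _random_cds(rng, 120)   # 360 nt
        cand = _candidate({"reference": dna, "a": dna})
        blocks = [
            PrimerBlock(0, 8, 1.0, [frozenset(c) for c in dna[:24]]),
            PrimerBlock(112, 8, 1.0, [frozenset(c) for c in dna[336:360]]),
        ]
        pairs = enumerate_inner_pairs(blocks, cand, CFG)
        assert len(pairs) == 1
        assert pairs[0].product_len_ref == 360

    def test_product_length_bounds(self):
        rng = np.random.default_rng(31)
        dna = _random_cds(rng, 100)   # 300 nt
        cand = _candidate({"reference": dna, "a": dna})
        blocks = [
            PrimerBlock(0, 8, 1.0, [frozenset(c) for c in dna[:24]]),
            PrimerBlock(76, 8, 1.0, [frozenset(c) for c in dna[228:252]]),   # product 252
            PrimerBlock(92, 8, 1.0, [frozenset(c) for c in dna[276:300]]),   # product 300
        ]
        pairs = enumerate_inner_pairs(blocks, cand, CFG)
        products = sorted(p.product_len_ref for p in pairs)
        assert 252 not in products       # below the 300 floor
        assert 300 in products

    def test_degeneracy_ceiling_filters_blocks(self):
        rng = np.random.default_rng(32)
        dna = _random_cds(rng, 120)
        cand = _candidate({"reference": dna, "a": dna})
        wide = [frozenset("ACGT")] * 24   # degeneracy 4^24
        blocks = [
            PrimerBlock(0, 8, 1.0, wide),
            PrimerBlock(112, 8, 1.0, [frozenset(c) for c in dna[336:360]]),
        ]
        assert enumerate_inner_pairs(blocks, cand, CFG) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_pair_count_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cand = _planted_candidate(rng)
        blocks = find_primer_blocks(cand, CFG)
        pairs = enumerate_inner_pairs(blocks, cand, CFG)
        view = _CandidateView(cand, CFG)
        lo, hi = CFG.inner_product_len_range_nt
        expected = 0
        for f in blocks:
            for r in blocks:
                if f.degeneracy > CFG.max_primer_degeneracy:
                    continue
                if r.degeneracy > CFG.max_primer_degeneracy:
                    continue
                if f.nt_end > r.nt_start:
                    continue
                product = view.ref_len(f.nt_start, r.nt_end)
                if lo <= product <= hi:
                    expected += 1
        assert len(pairs) == expected

    def test_lower_degeneracy_ceiling_never_increases_pairs(self):
        rng = np.random.default_rng(33)
        cand = _planted_candidate(rng)
        blocks = find_primer_blocks(cand, CFG)
        counts = []
        for ceiling in (8192, 512, 32, 1):
            cfg = CFG.replace(max_primer_degeneracy=ceiling)
            counts.append(len(enumerate_inner_pairs(blocks, cand, cfg)))
        assert counts == sorted(counts, reverse=True)


def _flank_candidate(outer_gap_codons):
    """identical rows; inner pair at a known position with an outer block
    exactly ``3*outer_gap_codons`` nt upstream of the inner forward block."""
    rng = np.random.default_rng(40)
    n = 8 + outer_gap_codons + 8 + 110 + 8
    dna = _random_cds(rng, n)
    cand = _candidate({"reference": dna, "a": dna})
    inner_f = PrimerBlock(8 + outer_gap_codons, 8, 1.0,
                          [frozenset(c) for c in dna[3 * (8 + outer_gap_codons): 3 * (16 + outer_gap_codons)]])
    inner_r = PrimerBlock(n - 8, 8, 1.0, [frozenset(c) for c in dna[3 * (n - 8):]])
    outer = PrimerBlock(0, 8, 1.0, [frozenset(c) for c in dna[:24]])
    inner = InnerPair(
        forward=build_degenerate_primer(inner_f, "forward"),
        reverse=build_degenerate_primer(inner_r, "reverse"),
        product_len_ref=_CandidateView(cand, CFG).ref_len(inner_f.nt_start, inner_r.nt_end),
    )
    return cand, inner, [outer, inner_f, inner_r]


class TestOuterPairs:
    def test_missing_outer_side_yields_nothing(self):
        # outer primers exist only "if they exist": no block right of inner_r
        cand, inner, blocks = _flank_candidate(100)
        sets = find_outer_pairs(inner, blocks, cand, CFG)
        assert sets == []

    def test_full_nested_geometry(self):
        rng = np.random.default_rng(41)
        cand = _planted_candidate(rng, flank_codons=30)
        blocks = find_primer_blocks(cand, CFG)
        pairs = enumerate_inner_pairs(blocks, cand, CFG)
        all_sets = []
        for pair in pairs[:: max(1, len(pairs) // 40)]:   # sample across the range
            all_sets.extend(find_outer_pairs(pair, blocks, cand, CFG))
        assert all_sets
        for s in all_sets:
            assert s.outer_f.block.nt_end <= s.inner_f.block.nt_start
            assert s.inner_r.block.nt_end <= s.outer_r.block.nt_start
            assert s.outer_product_len_ref >= s.inner_product_len_ref

    def test_flank_boundary_inclusion_exclusion(self):
        rng = np.random.default_rng(42)
        n = 8 + 150 + 8 + 110 + 8   # outer gap exactly 450 nt
        dna = _random_cds(rng, n)
        cand = _candidate({"reference": dna, "a": dna})
        view = _CandidateView(cand, CFG)

        def block_at(aa):
            return PrimerBlock(aa, 8, 1.0,
                               [frozenset(c) for c in dna[3 * aa: 3 * (aa + 8)]])

        outer_f = block_at(0)
        inner_f = block_at(158)
        inner_r = block_at(n - 8)
        outer_r_missing = block_at(n - 8)   # nothing right of inner_r
        inner = InnerPair(
            forward=build_degenerate_primer(inner_f, "forward"),
            reverse=build_degenerate_primer(inner_r, "reverse"),
            product_len_ref=view.ref_len(inner_f.nt_start, inner_r.nt_end),
        )
        # distance outer_f end (24+450) .. inner_f start = 450 -> allowed
        assert view.ref_len(outer_f.nt_end, inner_f.nt_start) == 450
        fwd_ok = [
            b for b in [outer_f]
            if b.nt_end <= inner_f.nt_start
            and view.ref_len(b.nt_end, inner_f.nt_start) <= CFG.outer_flank_nt
        ]
        assert fwd_ok == [outer_f]
        # pushing the inner pair one codon right makes the distance 453 -> excluded
        inner_f_far = block_at(159)
        assert view.ref_len(outer_f.nt_end, inner_f_far.nt_start) == 453
        inner_far = InnerPair(
            forward=build_degenerate_primer(inner_f_far, "forward"),
            reverse=build_degenerate_primer(inner_r, "reverse"),
            product_len_ref=view.ref_len(inner_f_far.nt_start, inner_r.nt_end),
        )
        sets = find_outer_pairs(inner_far, [outer_f, inner_f_far, inner_r], cand, CFG)
        assert sets == []

    def test_block_overlapping_inner_forward_excluded(self):
        rng = np.random.default_rng(43)
        n = 8 + 20 + 8 + 110 + 8
        dna = _random_cds(rng, n)
        cand = _candidate({"reference": dna, "a": dna})

        def block_at(aa):
            return PrimerBlock(aa, 8, 1.0,
                               [frozenset(c) for c in dna[3 * aa: 3 * (aa + 8)]])

        inner_f = block_at(28)
        inner_r = block_at(n - 8)
        overlapping = block_at(25)   # overlaps inner_f (25..33 vs 28..36)
        inner = InnerPair(
            forward=build_degenerate_primer(inner_f, "forward"),
            reverse=build_degenerate_primer(inner_r, "reverse"),
            product_len_ref=_CandidateView(cand, CFG).ref_len(inner_f.nt_start, inner_r.nt_end),
        )
        sets = find_outer_pairs(inner, [overlapping, inner_f, inner_r], cand, CFG)
        assert sets == []


def _perfect_primer(dna_block):
    block = PrimerBlock(0, 8, 1.0, [frozenset(c) for c in dna_block])
    return block


class TestScores:
    def test_four_perfect_primers_score_one(self):
        # conserved block, degeneracy 1, balanced GC, no homopolymer
        seq = "ATGCCAGTTGACGATTCGCATAGC"
        p = build_degenerate_primer(_perfect_primer(seq), "forward")
        r = build_degenerate_primer(_perfect_primer(seq), "reverse")
        nested = NestedPrimerSet(
            inner_f=p, inner_r=r, outer_f=p, outer_r=r,
            inner_product_len_ref=400, outer_product_len_ref=500,
        )
        assert score_pcr(nested, CFG) == pytest.approx(1.0)

    def test_degeneracy_at_ceiling_zeroes_term(self):
        unions = [frozenset("ACGT")] * 6 + [frozenset("AC")] + [frozenset("C")] * 17
        deg = 4 ** 6 * 2
        assert deg == CFG.max_primer_degeneracy
        block = PrimerBlock(0, 8, 1.0, unions)
        primer = build_degenerate_primer(block, "forward")
        from nestprimer.primers import _primer_score
        # conservation 1.0; complexity: GC fine? compute directly
        from nestprimer.primers import _primer_complexity
        expected = (1.0 + 0.0 + _primer_complexity(primer, CFG)) / 3.0
        assert _primer_score(primer, CFG) == pytest.approx(expected)

    def test_hand_computed_score_pcr(self):
        # primer with one 2-fold position away from the 3' end, similarity 0.75
        seq = "ATGCCAGTTGACGATTCGCATAGC"
        unions = [frozenset(c) for c in seq]
        unions[3] = frozenset("AG")
        block = PrimerBlock(0, 8, 0.75, unions)
        p = build_degenerate_primer(block, "forward")
        perfect = build_degenerate_primer(_perfect_primer(seq), "forward")
        perfect_r = build_degenerate_primer(_perfect_primer(seq), "reverse")
        nested = NestedPrimerSet(
            inner_f=p, inner_r=perfect_r, outer_f=perfect, outer_r=perfect_r,
            inner_product_len_ref=400, outer_product_len_ref=500,
        )
        import math
        deg_term = 1.0 - math.log(2) / math.log(8192)
        p_score = (0.75 + deg_term + 1.0) / 3.0
        expected = (p_score + 1.0 + 1.0 + 1.0) / 4.0
        assert score_pcr(nested, CFG) == pytest.approx(expected)

    def test_homopolymer_and_gc_penalties(self):
        from nestprimer.primers import _primer_complexity
        # 5 consecutive positions admitting 'A' in some expansion
        unions = [frozenset("A")] * 5 + [frozenset(c) for c in "CGCGCGCGCGCGCGCGCGC"]
        primer = build_degenerate_primer(PrimerBlock(0, 8, 1.0, unions), "forward")
        # homopolymer -0.25; GC = 19/24 > 0.70 -> -0.25
        assert _primer_complexity(primer, CFG) == pytest.approx(0.5)

    def test_three_prime_degeneracy_penalty(self):
        from nestprimer.primers import _primer_complexity
        seq = "ATGCCAGTTGACGATTCGCATAG"
        unions = [frozenset(c) for c in seq] + [frozenset("ACGT")]
        primer = build_degenerate_primer(PrimerBlock(0, 8, 1.0, unions), "forward")
        assert _primer_complexity(primer, CFG) == pytest.approx(0.5)
        # same block as a reverse primer: its 3' end is the template 5' end
        rev = build_degenerate_primer(PrimerBlock(0, 8, 1.0, unions), "reverse")
        assert _primer_complexity(rev, CFG) == pytest.approx(1.0)

    def test_score_infor_identical_rows_zero(self):
        rng = np.random.default_rng(50)
        cand = _planted_candidate(rng, divergence=0.0)
        blocks = find_primer_blocks(cand, CFG)
        pairs = enumerate_inner_pairs(blocks, cand, CFG)
        assert score_infor(pairs[0], cand, CFG) == 0.0

    def test_score_infor_saturated_at_cap(self):
        # two rows differing at every position between the primers
        rng = np.random.default_rng(51)
        block_dna = _random_cds(rng, 8)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        mid_ref = _random_cds(rng, 110)
        mid_alt = "".join(flip[c] for c in mid_ref)
        ref = block_dna + mid_ref + block_dna
        alt = block_dna + mid_alt + block_dna
        cand = _candidate({"reference": ref, "a": alt})
        inner_f = PrimerBlock(0, 8, 1.0, [frozenset(c) for c in block_dna])
        inner_r = PrimerBlock(118, 8, 1.0, [frozenset(c) for c in block_dna])
        inner = InnerPair(
            forward=build_degenerate_primer(inner_f, "forward"),
            reverse=build_degenerate_primer(inner_r, "reverse"),
            product_len_ref=378,
        )
        assert score_infor(inner, cand, CFG) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_score_infor_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cand = _planted_candidate(rng)
        blocks = find_primer_blocks(cand, CFG)
        pairs = enumerate_inner_pairs(blocks, cand, CFG)
        pair = pairs[len(pairs) // 2]
        start = pair.forward.block.nt_end
        end = pair.reverse.block.nt_start
        rows = list(cand.msa.rows.values())
        expected = min(1.0, brute_mean_p_distance(rows, start, end) / 0.5)
        assert score_infor(pair, cand, CFG) == pytest.approx(expected, abs=1e-12)


class TestTotalScore:
    def test_closed_form(self):
        assert total_score(0.8, 0.6, 1.0) == pytest.approx(0.7)

    def test_pis_zero_returns_infor(self):
        assert total_score(0.31, 0.87, 0.0) == pytest.approx(0.87)

    def test_large_pis_approaches_pcr(self):
        assert total_score(0.8, 0.1, 1e6) == pytest.approx(0.8, abs=1e-5)

    def test_negative_pis_rejected(self):
        with pytest.raises(ValueError):
            total_score(0.5, 0.5, -1.0)

    @pytest.mark.parametrize("pis", [0.0, 0.5, 1.0, 3.0])
    def test_grid_matches_formula_and_monotonicity(self, pis):
        rng = np.random.default_rng(60)
        for _ in range(25):
            s1, s2 = rng.random(), rng.random()
            assert total_score(s1, s2, pis) == pytest.approx((pis * s1 + s2) / (1 + pis))
        # affine in ScoreINFOR, strictly increasing in both for pis > 0
        if pis > 0:
            assert total_score(0.6, 0.5, pis) > total_score(0.5, 0.5, pis)
            assert total_score(0.5, 0.6, pis) > total_score(0.5, 0.5, pis)
        d1 = total_score(0.5, 0.4, pis) - total_score(0.5, 0.3, pis)
        d2 = total_score(0.5, 0.9, pis) - total_score(0.5, 0.8, pis)
        assert d1 == pytest.approx(d2)


class TestSelection:
    def _scored(self, total, product=400, start=0, tag="A"):
        rng = np.random.default_rng(70)
        seq = _random_cds(rng, 8)
        block = PrimerBlock(start // 3, 8, 1.0, [frozenset(c) for c in seq])
        p = build_degenerate_primer(block, "forward")
        r = build_degenerate_primer(block, "reverse")
        return NestedPrimerSet(
            inner_f=p, inner_r=r, outer_f=p, outer_r=r,
            inner_product_len_ref=product, outer_product_len_ref=product + 100,
            score_pcr=total, score_infor=total, total_score=total,
        )

    def test_highest_score_wins(self):
        a, b = self._scored(0.71), self._scored(0.70)
        assert select_best_per_msa([b, a]) is a

    def test_tie_broken_by_product_then_position(self):
        a = self._scored(0.7, product=500)
        b = self._scored(0.7, product=400)
        assert select_best_per_msa([b, a]) is a
        c = self._scored(0.7, product=400, start=0)
        d = self._scored(0.7, product=400, start=30)
        assert select_best_per_msa([d, c]) is c

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_best_per_msa([])

    @pytest.mark.parametrize("seed", range(4))
    def test_fast_selection_equals_exhaustive(self, seed):
        """The vectorised pipeline path picks the same nested set as the
        brute-force enumeration."""
        rng = np.random.default_rng(seed)
        cand = _planted_candidate(rng, mid_codons=100, flank_codons=12, n_rows=4)
        fast = design_primers_for_candidate(cand, CFG)
        brute = design_primers_brute(cand, CFG)
        assert (fast is None) == (brute is None)
        if fast is not None:
            assert fast.total_score == pytest.approx(brute.total_score)
            assert (
                fast.outer_f.iupac, fast.inner_f.iupac,
                fast.inner_r.iupac, fast.outer_r.iupac,
            ) == (
                brute.outer_f.iupac, brute.inner_f.iupac,
                brute.inner_r.iupac, brute.outer_r.iupac,
            )
            assert fast.inner_product_len_ref == brute.inner_product_len_ref


class TestEmit:
    def test_zero_loci_header_only(self, tmp_path):
        emit_outputs({}, {}, tmp_path)
        table = (tmp_path / "primer_table.tsv").read_text().splitlines()
        assert len(table) == 1
        assert (tmp_path / "reference_NPCLs.dna.fasta").read_text() == ""

    def test_reference_sequences_ungapped_and_in_frame(self, tmp_path):
        rng = np.random.default_rng(80)
        cand = _planted_candidate(rng)
        nested = design_primers_for_candidate(cand, CFG)
        assert nested is not None
        emit_outputs({"locusA": nested}, {"locusA": cand}, tmp_path)
        from nestprimer.io import read_fasta
        dna = read_fasta(tmp_path / "reference_NPCLs.dna.fasta", "dna")
        pep = read_fasta(tmp_path / "reference_NPCLs.pep.fasta", "protein")
        assert len(dna) == len(pep) == 1
        assert "-" not in dna[0].seq
        assert len(dna[0].seq) % 3 == 0
        table = (tmp_path / "primer_table.tsv").read_text().splitlines()
        assert len(table) == 2
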