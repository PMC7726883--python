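"""Alignment-layer tests, checked against independent oracles:

- an affine-gap dynamic program written here (memoized recursion, no shared
  code with the implementation) for optimal scores on short strings;
- exhaustive enumeration of all alignments on tiny strings to validate that
  oracle itself;
- enumeration of equivalent gap placements for the left-justify fixed point.
"""

import random
from functools import lru_cache

import pytest
from hypothesis import given, strategies as st

from mitobench.circular_alignment import (
    DEFAULT_SCORING,
    PairwiseAlignment,
    Scoring,
    global_align,
    left_justify,
    normalize_orientation,
    p_distance,
)
from mitobench.core_io import CircularSeq

S = DEFAULT_SCORING


def oracle_affine_score(a: str, b: str, sc: Scoring = S) -> int:
    """Optimal global affine-gap score by memoized recursion (Gotoh states)."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = last column was diagonal, 1 = gap in b, 2 = gap in a
        if i == 0 and j == 0:
            # only the neutral start state exists; a gap at the sequence
            # start must still pay gap_open
            return 0 if state == 0 else NEG
        best = NEG
        if i > 0 and j > 0:
            sub = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            if state == 0:
                best = max(best, max(rec(i - 1, j - 1, s) for s in range(3)) + sub)
        if i > 0 and state == 1:  # a[i-1] aligned to gap
            best = max(best, rec(i - 1, j, 1) + sc.gap_extend)
            best = max(best, max(rec(i - 1, j, s) for s in (0, 2))
                       + sc.gap_open + sc.gap_extend)
        if j > 0 and state == 2:
            best = max(best, rec(i, j - 1, 2) + sc.gap_extend)
            best = max(best, max(rec(i, j - 1, s) for s in (0, 1))
                       + sc.gap_open + sc.gap_extend)
        return best

    return int(max(rec(len(a), len(b), s) for s in range(3)))


def enumerate_alignments(a: str, b: str):
    """Every global alignment of a and b as (ref_row, qry_row) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for r, q in enumerate_alignments(a[:-1], b):
            yield r + a[-1], q + "-"
    if b:
        for r, q in enumerate_alignments(a, b[:-1]):
            yield r + "-", q + b[-1]
    if a and b:
        for r, q in enumerate_alignments(a[:-1], b[:-1]):
            yield r + a[-1], q + b[-1]


def row_score(r: str, q: str, sc: Scoring = S) -> int:
    return PairwiseAlignment(ref_row=r, qry_row=q, score=0).column_score(sc)


def test_affine_oracle_matches_exhaustive_enumeration():
    rng = random.Random(11)
    for _ in range(30):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
        brute = max(row_score(r, q) for r, q in enumerate_alignments(a, b))
        assert oracle_affine_score(a, b) == brute


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align(CircularSeq(id="r", seq="ACGT"),
                           CircularSeq(id="q", seq="ACGT"))
        assert (aln.ref_row, aln.qry_row, aln.score) == ("ACGT", "ACGT", 4)

    def test_single_base_gap_costs_open_plus_extend(self):
        # 4 matches + one length-1 gap (-4 - 2) = -2
        aln = global_align(CircularSeq(id="r", seq="AAATG"),
                           CircularSeq(id="q", seq="AATG"))
        assert aln.score == 4 - 6
        assert aln.qry_row.count("-") == 1 and aln.ref_row.count("-") == 0

    def test_forced_mismatch_column(self):
        aln = global_align(CircularSeq(id="r", seq="ACGT"),
                           CircularSeq(id="q", seq="AGGT"))
        assert aln.score == 1 - 2 + 1 + 1
        assert sum(r != q for r, q in zip(aln.ref_row, aln.qry_row)) == 1

    def test_score_equals_oracle_on_short_strings(self):
        rng = random.Random(5)
        for _ in range(100):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 10)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 10)))
            aln = global_align(CircularSeq(id="r", seq=a), CircularSeq(id="q", seq=b))
            assert aln.score == oracle_affine_score(a, b)
            assert aln.column_score() == aln.score
            assert aln.ref_seq == a and aln.qry_seq == b

    def test_rows_must_have_equal_length_and_no_gap_gap_column(self):
        with pytest.raises(ValueError, match="length"):
            PairwiseAlignment(ref_row="AC", qry_row="A", score=0)
        with pytest.raises(ValueError, match="gap/gap"):
            PairwiseAlignment(ref_row="A-C", qry_row="A-C", score=0)


class TestLeftJustify:
    def test_all_equivalent_gap_placements_share_one_fixed_point(self):
        # a deletion gap inside a homopolymer run can sit at any offset in
        # the run; every placement is equivalent and must collapse to the
        # single canonical form with the gap at the run start
        rng = random.Random(3)
        for _ in range(40):
            b = rng.choice("ACGT")
            others = [c for c in "ACGT" if c != b]
            left = "".join(rng.choice(others) for _ in range(rng.randint(1, 3)))
            run = b * rng.randint(2, 5)
            right = "".join(rng.choice(others) for _ in range(rng.randint(1, 3)))
            ref = left + run + right
            d = rng.randint(1, len(run) - 1) if len(run) > 1 else 1
            start = len(left)
            placements = set()
            for off in range(len(run) - d + 1):
                pos = start + off
                qry_row = ref[:pos] + "-" * d + ref[pos + d:]
                lj = left_justify(PairwiseAlignment(ref_row=ref, qry_row=qry_row, score=0))
                assert lj.ref_row == ref and lj.qry_seq == ref[:pos] + ref[pos + d:]
                placements.add((lj.ref_row, lj.qry_row))
            assert len(placements) == 1
            ((_, q),) = placements
            assert q[start] == "-"

    def test_every_optimal_alignment_left_justifies_to_a_fixed_point(self):
        rng = random.Random(4)
        for _ in range(15):
            a = "".join(rng.choice("AT") for _ in range(rng.randint(2, 6)))
            b = "".join(rng.choice("AT") for _ in range(rng.randint(2, 6)))
            best = oracle_affine_score(a, b)
            for r, q in enumerate_alignments(a, b):
                if row_score(r, q) != best:
                    continue
                lj = left_justify(PairwiseAlignment(ref_row=r, qry_row=q, score=best))
                again = left_justify(lj)
                assert (again.ref_row, again.qry_row) == (lj.ref_row, lj.qry_row)
                assert lj.column_score() == best

    def test_gap_in_homopolymer_moves_to_run_start(self):
        aln = PairwiseAlignment(ref_row="AAAT", qry_row="AA-T", score=0)
        lj = left_justify(aln)
        assert lj.qry_row == "-AAT"
        assert lj.ref_row == "AAAT"

    def test_preserves_sequences_and_column_score(self):
        rng = random.Random(9)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 9)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 9)))
            aln = global_align(CircularSeq(id="r", seq=a), CircularSeq(id="q", seq=b))
            lj = left_justify(aln)
            assert lj.ref_seq == a and lj.qry_seq == b
            assert lj.column_score() == aln.column_score()

    def test_idempotent(self):
        aln = PairwiseAlignment(ref_row="ACCCGT--A", qry_row="A-CCGTTTA", score=0)
        once = left_justify(aln)
        assert left_justify(once) == once

    def test_gapless_alignment_unchanged(self):
        aln = PairwiseAlignment(ref_row="ACGT", qry_row="AGGT", score=1)
        assert left_justify(aln) == aln


class TestPDistance:
    def test_identical_sequences_have_zero_distance(self):
        row = "ACGT" * 25
        assert p_distance(PairwiseAlignment(ref_row=row, qry_row=row, score=100)) == 0.0

    def test_direct_count(self):
        aln = PairwiseAlignment(ref_row="ACGT", qry_row="ACGA", score=0)
        assert p_distance(aln) == 0.25

    def test_pairwise_deletion_excludes_gap_and_n_columns(self):
        aln = PairwiseAlignment(ref_row="AC-GT", qry_row="ACNNA", score=0)
        # columns: A/A, C/C, skip gap, G/N skip, T/A -> 1 diff / 3 comparable
        assert p_distance(aln) == pytest.approx(1 / 3)

    def test_no_comparable_sites_is_an_error(self):
        aln = PairwiseAlignment(ref_row="NN-", qry_row="AAN", score=0)
        with pytest.raises(ValueError, match="comparable"):
            p_distance(aln)

    @given(st.text(alphabet="ACGTN-", min_size=1, max_size=30))
    def test_symmetric_in_rows(self, row):
        other = row[::-1]
        # build a gap/gap-free pair of rows of equal length
        ref, qry = [], []
        for r, q in zip(row, other):
            if r == "-" and q == "-":
                continue
            ref.append(r)
            qry.append(q)
        if not ref:
            return
        a = PairwiseAlignment(ref_row="".join(ref), qry_row="".join(qry), score=0)
        b = PairwiseAlignment(ref_row="".join(qry), qry_row="".join(ref), score=0)
        try:
            assert p_distance(a) == p_distance(b)
        except ValueError:
            with pytest.raises(ValueError):
                p_distance(b)

    def test_column_count_oracle_on_random_alignments(self):
        rng = random.Random(17)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 10)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 10)))
            aln = global_align(CircularSeq(id="r", seq=a), CircularSeq(id="q", seq=b))
            acgt = set("ACGT")
            comp = [(r, q) for r, q in zip(aln.ref_row, aln.qry_row)
                    if r in acgt and q in acgt]
            expected = sum(r != q for r, q in comp) / len(comp)
            assert p_distance(aln) == pytest.approx(expected)


class TestNormalizeOrientation:
    def test_exact_rotation_recovery(self, small_genome):
        genome, _ = small_genome
        rotated = genome.rotated(1000)
        normalized, orient = normalize_orientation(rotated, genome)
        assert normalized.seq == genome.seq
        assert orient.strand == "forward" and orient.anchor_matched

    def test_reverse_complement_rotation_recovery(self, small_genome):
        genome, _ = small_genome
        flipped = genome.reverse_complement().rotated(37)
        normalized, orient = normalize_orientation(flipped, genome)
        assert normalized.seq == genome.seq
        assert orient.strand == "reverse_complement" and orient.anchor_matched

    def test_mutated_anchor_falls_back_to_grid_minimum(self):
        rng = random.Random(2)
        seq = "".join(rng.choice("ACGT") for _ in range(2000))
        ref = CircularSeq(id="r", seq=seq, circular=True)
        asm = list(ref.rotated(500).seq)
        # destroy every occurrence of the anchor k-mer
        asm[1500] = {"A": "C", "C": "A", "G": "T", "T": "G"}[asm[1500]]
        asm = CircularSeq(id="q", seq="".join(asm), circular=True)
        normalized, orient = normalize_orientation(asm, ref, k=31)
        assert not orient.anchor_matched

        import edlib

        # exhaustive search over all rotations x strands
        best = float("inf")
        for cand in (asm, asm.reverse_complement()):
            for off in range(len(asm)):
                d = edlib.align(cand.rotated(off).seq, ref.seq, mode="NW",
                                task="distance")["editDistance"]
                best = min(best, d)
        grid_best = edlib.align(normalized.seq, ref.seq, mode="NW",
                                task="distance")["editDistance"]
        # the L/8 grid is approximate: it must be within one grid spacing of
        # the exhaustive optimum (each offset step costs at most 2 edits/base)
        assert grid_best >= best
        candidates = []
        for strand, cand in (("f", asm), ("r", asm.reverse_complement())):
            for off in sorted({i * len(asm) // 8 for i in range(8)}):
                candidates.append(edlib.align(cand.rotated(off).seq, ref.seq,
                                              mode="NW", task="distance")["editDistance"])
        assert grid_best == min(candidates)

    def test_k_larger_than_sequence_is_an_error(self):
        ref = CircularSeq(id="r", seq="ACGTACGT", circular=True)
        with pytest.raises(ValueError, match="k="):
            normalize_orientation(ref, ref, k=100)

    def test_linear_assembly_keeps_offset_zero(self, small_genome):
        genome, _ = small_genome
        linear = CircularSeq(id="lin", seq=genome.seq, circular=False)
        _, orient = normalize_orientation(linear.reverse_complement(), genome)
        assert orient.offset == 0
        assert orient.strand == "reverse_complement"
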