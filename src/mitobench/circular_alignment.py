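"""Rotation/strand normalization and canonical global pairwise alignment.

A circular assembly has an arbitrary start position and strand relative to
the reference. ``normalize_orientation`` places it in the reference frame by
anchoring the reference's first k-mer in the doubled assembly (exact match on
either strand), falling back to a coarse rotation grid scored by edit
distance. The normalized pair is then aligned globally with affine gap costs
and the alignment is left-justified so that indels in homopolymer runs sit at
a canonical (leftmost) position — a precondition for reproducible error
classification.

Circularity is handled by rotation followed by linear alignment; there is no
cyclic dynamic program. Residual end effects are bounded by the largest
terminal indel and show up in the error profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib
from Bio import Align

from mitobench.core_io import CircularSeq


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; a gap of length k scores gap_open + k*gap_extend.

    Defaults make a length-k homopolymer indel cheaper than k substitutions,
    mirroring the indel-dominated error structure of nanopore assemblies.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class Orientation:
    """How an assembly was mapped onto the reference frame.

    ``offset`` is the position (on the strand-corrected assembly) rotated to
    the start; ``anchor_matched`` records whether the reference-start k-mer
    was found exactly.
    """

    offset: int
    strand: str  # "forward" | "reverse_complement"
    anchor_matched: bool

    def to_json_dict(self) -> dict:
        return {
            "offset": self.offset,
            "strand": self.strand,
            "anchor_matched": self.anchor_matched,
        }


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gapped global alignment of reference and query rows.

    Rows have equal length, no column is gap/gap, and removing '-' from each
    row reproduces the ungapped sequence.
    """

    ref_row: str
    qry_row: str
    score: int
    ref_id: str = "ref"
    qry_id: str = "qry"

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.qry_row):
            raise ValueError("alignment rows differ in length")
        for i, (r, q) in enumerate(zip(self.ref_row, self.qry_row)):
            if r == "-" and q == "-":
                raise ValueError(f"gap/gap column at {i}")

    @property
    def ref_seq(self) -> str:
        return self.ref_row.replace("-", "")

    @property
    def qry_seq(self) -> str:
        return self.qry_row.replace("-", "")

    def column_score(self, scoring: Scoring = DEFAULT_SCORING) -> int:
        """Score recomputed from the rows (for cross-checking ``score``)."""
        total = 0
        for row in (self.ref_row, self.qry_row):
            i = 0
            while i < len(row):
                if row[i] == "-":
                    j = i
                    while j < len(row) and row[j] == "-":
                        j += 1
                    total += scoring.gap_open + scoring.gap_extend * (j - i)
                    i = j
                else:
                    i += 1
        for r, q in zip(self.ref_row, self.qry_row):
            if r != "-" and q != "-":
                total += scoring.match if r == q else scoring.mismatch
        return total

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.ref_id}\n{self.ref_row}\n>{self.qry_id}\n{self.qry_row}\n")


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def normalize_orientation(
    assembly: CircularSeq, reference: CircularSeq, k: int = 31
) -> tuple[CircularSeq, Orientation]:
    """Rotate (and possibly reverse-complement) ``assembly`` onto the reference frame.

    The k-mer at reference position 0 is searched exactly in the doubled
    assembly, forward strand first; if found, the assembly is rotated so that
    the anchor starts the sequence (``anchor_matched=True``). If the anchor is
    absent on both strands, the orientation minimizing edit distance to the
    reference over 8 rotations at L/8 spacing x 2 strands is chosen
    (``anchor_matched=False``, documented as approximate).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(len(assembly), len(reference)):
        raise ValueError(
            f"k={k} exceeds min sequence length {min(len(assembly), len(reference))}"
        )

    candidates = [("forward", assembly), ("reverse_complement", assembly.reverse_complement())]

    if not assembly.circular:
        # No rotation possible; choose strand by edit distance, offset fixed at 0.
        best = min(
            candidates, key=lambda c: (_edit_distance(c[1].seq, reference.seq), c[0] != "forward")
        )
        return best[1], Orientation(offset=0, strand=best[0], anchor_matched=False)

    anchor = reference.seq[:k]
    L = len(assembly)
    for strand, seq in candidates:
        doubled = seq.seq + seq.seq[: L - 1]
        hit = doubled.find(anchor)
        if hit != -1:
            return seq.rotated(hit), Orientation(offset=hit, strand=strand, anchor_matched=True)

    # Fallback: coarse rotation grid scored by edit distance.
    grid = sorted({(i * L) // 8 for i in range(8)})
    best_key, best_seq, best_orient = None, None, None
    for strand, seq in candidates:
        for off in grid:
            rot = seq.rotated(off)
            key = (_edit_distance(rot.seq, reference.seq), strand != "forward", off)
            if best_key is None or key < best_key:
                best_key, best_seq = key, rot
                best_orient = Orientation(offset=off, strand=strand, anchor_matched=False)
    return best_seq, best_orient


def global_align(
    reference: CircularSeq,
    assembly: CircularSeq,
    scoring: Scoring = DEFAULT_SCORING,
) -> PairwiseAlignment:
    """Optimal global alignment of the (orientation-normalized) assembly.

    Affine gap costs; the first optimal traceback is taken and should be
    canonicalized with :func:`left_justify` before event extraction.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score for the first gap base.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    result = aligner.align(reference.seq, assembly.seq)
    aln = result[0]
    return PairwiseAlignment(
        ref_row=str(aln[0]),
        qry_row=str(aln[1]),
        score=int(result.score),
        ref_id=reference.id,
        qry_id=assembly.id,
    )


def left_justify(alignment: PairwiseAlignment) -> PairwiseAlignment:
    """Shift every gap run leftward as far as an equivalent placement exists.

    A gap run may move one column left when the character displaced from its
    left edge re-pairs with an identical partner at the right edge, so the
    ungapped rows, the match/mismatch counts, and the gap run lengths (hence
    score and edit distance) are all preserved. Idempotent; the fixed point is
    the canonical form assumed by event extraction.
    """
    ref = list(alignment.ref_row)
    qry = list(alignment.qry_row)
    n = len(ref)

    changed = True
    while changed:
        changed = False
        for row, other in ((ref, qry), (qry, ref)):
            i = 0
            while i < n:
                if row[i] != "-":
                    i += 1
                    continue
                a = i
                b = i
                while b + 1 < n and row[b + 1] == "-":
                    b += 1
                # shift run [a, b] left while equivalent
                while a > 0 and other[a - 1] != "-" and other[a - 1] == other[b]:
                    row[b] = row[a - 1]
                    row[a - 1] = "-"
                    a -= 1
                    b -= 1
                    changed = True
                i = b + 1
    out = PairwiseAlignment(
        ref_row="".join(ref),
        qry_row="".join(qry),
        score=alignment.score,
        ref_id=alignment.ref_id,
        qry_id=alignment.qry_id,
    )
    return out


def p_distance(alignment: PairwiseAlignment) -> float:
    """Proportion of differing sites among comparable aligned sites.

    Pairwise deletion: columns containing a gap or an N in either row are
    excluded from numerator and denominator. Zero means the two sequences are
    identical over all comparable sites.
    """
    comparable = 0
    diff = 0
    acgt = frozenset("ACGT")
    for r, q in zip(alignment.ref_row, alignment.qry_row):
        if r in acgt and q in acgt:
            comparable += 1
            if r != q:
                diff += 1
    if comparable == 0:
        raise ValueError("no comparable sites (all columns gapped or ambiguous)")
    return diff / comparable
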