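"""Homopolymer-aware classification of assembly errors.

Every differing column of a canonical (left-justified) alignment is assigned
to exactly one discrete event: a maximal run of gap columns in one row is one
indel event, and each mismatch column is one substitution. Events are then
classified against the REFERENCE sequence context: an indel of 1-5 identical
bases is a homopolymer insertion/deletion of that multiplicity when the
reference run of that base at the site is at least ``hp_min_run`` (3) bases
long — the signature error mode of nanopore assemblies. Everything else falls
into length-based bins (single/short insertion or deletion, substitution),
with an overflow bin for events longer than any named category so that the
profile always accounts for every event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from mitobench.circular_alignment import PairwiseAlignment, left_justify
from mitobench.core_io import CircularSeq

#: Fixed category order used in every profile, table and report.
CATEGORIES: tuple[str, ...] = (
    "hp_del_1",
    "hp_del_2",
    "hp_del_3",
    "hp_del_4",
    "hp_del_5",
    "hp_ins_1",
    "hp_ins_2",
    "hp_ins_3",
    "hp_ins_4",
    "hp_ins_5",
    "substitution",
    "single_insertion",
    "short_insertion",
    "single_deletion",
    "short_deletion",
    "long_indel_other",
)


@dataclass(frozen=True)
class TaxonomyConfig:
    """Classification thresholds.

    hp_min_run: minimum reference run length for a homopolymer category.
    hp_max_len: largest indel length with a named homopolymer category
        (single..quintuple).
    short_ins_max / short_del_max: upper bounds of the non-homopolymer
        "short" bins; longer events fall into the overflow bin.
    """

    hp_min_run: int = 3
    hp_max_len: int = 5
    short_ins_max: int = 5
    short_del_max: int = 3


DEFAULT_TAXONOMY = TaxonomyConfig()


@dataclass(frozen=True)
class ErrorEvent:
    """One classified difference between assembly and reference.

    ref_pos is 0-based: for deletions/substitutions the first affected
    reference base, for insertions the reference insertion point (index of
    the next reference base). Exactly one of substitution / insertion /
    deletion holds. ``hp_base``/``hp_run_len`` are set only for homopolymer
    categories.
    """

    ref_pos: int
    ref_allele: str
    alt_allele: str
    category: str | None = None
    hp_base: str | None = None
    hp_run_len: int = 0

    def __post_init__(self) -> None:
        sub = len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        ins = self.ref_allele == "" and self.alt_allele != ""
        dele = self.alt_allele == "" and self.ref_allele != ""
        if sub and self.ref_allele == self.alt_allele:
            raise ValueError("substitution with identical alleles")
        if not (sub or ins or dele):
            raise ValueError(
                f"event at {self.ref_pos} is neither substitution, insertion "
                f"nor deletion: {self.ref_allele!r} -> {self.alt_allele!r}"
            )
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def is_insertion(self) -> bool:
        return self.ref_allele == ""

    @property
    def is_deletion(self) -> bool:
        return self.alt_allele == ""

    @property
    def is_substitution(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class ErrorProfile:
    """Per-category event counts in the fixed taxonomy order."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {c: int(self.counts.get(c, 0)) for c in CATEGORIES}
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in full.values()):
            raise ValueError("negative count")
        object.__setattr__(self, "counts", full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, category: str) -> int:
        return self.counts[category]

    def __eq__(self, other) -> bool:
        return isinstance(other, ErrorProfile) and self.counts == other.counts

    def top_category(self) -> str:
        return max(CATEGORIES, key=lambda c: (self.counts[c], -CATEGORIES.index(c)))

    def to_dict(self) -> dict[str, int]:
        return dict(self.counts, total=self.total)


def extract_events(alignment: PairwiseAlignment) -> list[ErrorEvent]:
    """Segment a left-justified alignment into discrete, unclassified events.

    Each maximal run of gap columns in one row is one indel event; each
    mismatch column is one substitution. Columns where either row is N
    produce no event (gap runs touching an N are dropped whole and a
    substitution against N is not scored). Raises if the alignment is not in
    canonical left-justified form.
    """
    if left_justify(alignment) != alignment:
        raise ValueError("alignment is not left-justified; canonicalize first")

    ref_row, qry_row = alignment.ref_row, alignment.qry_row
    events: list[ErrorEvent] = []
    ref_pos = 0  # reference coordinate of the current column's ref base
    i = 0
    n = len(ref_row)
    while i < n:
        r, q = ref_row[i], qry_row[i]
        if r == "-" or q == "-":
            in_ref = r == "-"  # gap in reference row -> insertion in assembly
            j = i
            row = ref_row if in_ref else qry_row
            while j < n and row[j] == "-":
                j += 1
            ref_seg = ref_row[i:j]
            qry_seg = qry_row[i:j]
            if "N" not in ref_seg and "N" not in qry_seg:
                if in_ref:
                    events.append(
                        ErrorEvent(ref_pos=ref_pos, ref_allele="", alt_allele=qry_seg)
                    )
                else:
                    events.append(
                        ErrorEvent(ref_pos=ref_pos, ref_allele=ref_seg, alt_allele="")
                    )
            if not in_ref:
                ref_pos += j - i
            i = j
        else:
            if r != q and r != "N" and q != "N":
                events.append(
                    ErrorEvent(ref_pos=ref_pos, ref_allele=r, alt_allele=q)
                )
            ref_pos += 1
            i += 1
    return events


def _run_extent(seq: str, pos: int, circular: bool) -> tuple[str, int]:
    """Length of the maximal run of seq[pos]'s base containing ``pos``.

    On a circular sequence the run may wrap the origin.
    """
    L = len(seq)
    b = seq[pos]
    length = 1
    j = pos
    for _ in range(L - 1):  # rightwards
        nj = j + 1
        if nj >= L:
            if not circular:
                break
            nj = 0
        if seq[nj] != b:
            break
        length += 1
        j = nj
    j = pos
    while length < L:  # leftwards
        pj = j - 1
        if pj < 0:
            if not circular:
                break
            pj = L - 1
        if seq[pj] != b:
            break
        length += 1
        j = pj
    return b, length


def _flank_run(seq: str, point: int, base: str, circular: bool) -> int:
    """Longest run of ``base`` immediately left or right of insertion ``point``."""
    L = len(seq)

    def run(start: int, step: int) -> int:
        n = 0
        idx = start
        while n < L:
            if idx < 0 or idx >= L:
                if not circular:
                    break
                idx %= L
            if seq[idx] != base:
                break
            n += 1
            idx += step
        return n

    right = run(point, +1) if (point < L or circular) else 0
    left = run(point - 1, -1) if (point > 0 or circular) else 0
    return max(left, right)


def classify_event(
    event: ErrorEvent,
    reference: CircularSeq,
    config: TaxonomyConfig = DEFAULT_TAXONOMY,
) -> ErrorEvent:
    """Assign a taxonomy category to one event (homopolymer context on the reference).

    Deletion of d identical bases b: ``hp_del_d`` when the reference run of b
    containing the deleted stretch is >= hp_min_run and d <= hp_max_len;
    otherwise single/short deletion by length, overflow beyond. Insertion of i
    identical bases b: ``hp_ins_i`` when the flanking reference run of b on
    either side of the insertion point is >= hp_min_run and i <= hp_max_len.
    Mixed-base indels are never homopolymer. Mismatches are substitutions.
    """
    if event.category is not None:
        raise ValueError(f"event at {event.ref_pos} already classified")
    seq = reference.seq
    circ = reference.circular

    if event.is_substitution:
        return replace(event, category="substitution")

    if event.is_deletion:
        d = len(event.ref_allele)
        bases = set(event.ref_allele)
        if len(bases) == 1:
            b, run = _run_extent(seq, event.ref_pos, circ)
            if run >= config.hp_min_run and d <= config.hp_max_len:
                return replace(event, category=f"hp_del_{d}", hp_base=b, hp_run_len=run)
        if d == 1:
            return replace(event, category="single_deletion")
        if d <= config.short_del_max:
            return replace(event, category="short_deletion")
        return replace(event, category="long_indel_other")

    # insertion
    i = len(event.alt_allele)
    bases = set(event.alt_allele)
    if len(bases) == 1:
        b = event.alt_allele[0]
        run = _flank_run(seq, event.ref_pos, b, circ)
        if run >= config.hp_min_run and i <= config.hp_max_len:
            return replace(event, category=f"hp_ins_{i}", hp_base=b, hp_run_len=run)
    if i == 1:
        return replace(event, category="single_insertion")
    if i <= config.short_ins_max:
        return replace(event, category="short_insertion")
    return replace(event, category="long_indel_other")


def classify_events(
    events: Iterable[ErrorEvent],
    reference: CircularSeq,
    config: TaxonomyConfig = DEFAULT_TAXONOMY,
) -> list[ErrorEvent]:
    return [classify_event(e, reference, config) for e in events]


def profile(events: Sequence[ErrorEvent]) -> ErrorProfile:
    """Aggregate classified events into a per-category histogram.

    The total counts events, not bases.
    """
    counts = {c: 0 for c in CATEGORIES}
    for e in events:
        if e.category is None:
            raise ValueError(f"unclassified event at ref_pos {e.ref_pos}")
        counts[e.category] += 1
    return ErrorProfile(counts=counts)


def events_to_tsv(events: Sequence[ErrorEvent], path) -> None:
    """Export events as TSV; ref_pos is 1-based in the export."""
    with open(path, "w") as fh:
        fh.write("ref_pos\tref_allele\talt_allele\tcategory\thp_base\thp_run_len\n")
        for e in events:
            fh.write(
                f"{e.ref_pos + 1}\t{e.ref_allele or '.'}\t{e.alt_allele or '.'}\t"
                f"{e.category or '.'}\t{e.hp_base or '.'}\t{e.hp_run_len}\n"
            )
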