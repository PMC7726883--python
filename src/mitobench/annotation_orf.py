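"""Annotation liftover and ORF-integrity checks under the invertebrate
mitochondrial genetic code (NCBI translation table 5).

Indel errors in an assembly shift protein-coding genes out of frame, which
scatters in-frame stop codons through their translations. Counting internal
stops after lifting the reference annotation onto the assembly through the
pairwise alignment is therefore a functional-annotation accuracy proxy: an
error-free assembly shows zero internal stops in every PCG, while a single
uncorrected homopolymer deletion almost always interrupts the reading frame.

Stops are counted in the annotated frame only; no attempt is made to find a
restored downstream frame. Incomplete terminal stop codons (T / TA, completed
by polyadenylation in mitochondria) are tolerated: trailing sub-codon bases
are ignored but reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from mitobench.circular_alignment import PairwiseAlignment
from mitobench.core_io import CircularSeq, GeneAnnotation, GeneKind, _COMPLEMENT


class GeneAbsentError(ValueError):
    """The gene interval has no aligned bases in the assembly."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon→amino-acid table; stops map to '*'."""

    name: str
    table: dict[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code {self.name!r} maps {len(self.table)} codons, not 64")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")


def invertebrate_mito_code() -> GeneticCode:
    """NCBI translation table 5 (invertebrate mitochondrial).

    AGA/AGG encode serine (not stop/arginine); stops are TAA and TAG only;
    ATT/ATC/ATA/ATG/GTG (among others) are permitted starts.
    """
    bio = CodonTable.unambiguous_dna_by_id[5]
    table = dict(bio.forward_table)
    for stop in bio.stop_codons:
        table[stop] = "*"
    return GeneticCode(
        name="invertebrate_mitochondrial",
        table=table,
        start_codons=frozenset(bio.start_codons),
    )


@dataclass(frozen=True)
class OrfReport:
    """ORF integrity of one lifted protein-coding gene.

    ``internal_stops`` counts '*' in the translation excluding the final
    codon; ``frame_intact`` records whether the lifted length is a multiple
    of 3. ``length_delta`` is lifted length minus reference gene length
    (None when the reference length was not supplied). A gene with
    ``gene_absent`` has no aligned bases and undefined stop counts.
    """

    gene: str
    lifted_start: int
    lifted_end: int
    frame_intact: bool
    internal_stops: int | None
    length_delta: int | None
    gene_absent: bool = False


def _ref_to_qry_maps(alignment: PairwiseAlignment) -> tuple[list[int], list[int]]:
    """Per-reference-base assembly coordinates.

    aligned_at[r] = assembly coordinate aligned to reference base r, or -1 if
    that base is deleted; qry_before[r] = number of assembly bases consumed
    before reference base r's column (insertion point mapping).
    """
    aligned_at: list[int] = []
    qry_before: list[int] = []
    q = 0
    for rc, qc in zip(alignment.ref_row, alignment.qry_row):
        if rc != "-":
            qry_before.append(q)
            aligned_at.append(q if qc != "-" else -1)
        if qc != "-":
            q += 1
    return aligned_at, qry_before


def liftover(ann: GeneAnnotation, alignment: PairwiseAlignment) -> GeneAnnotation:
    """Transfer one reference annotation onto assembly coordinates.

    The lifted start is the assembly coordinate of the first reference base
    at/after ``ann.start`` that is aligned to an assembly base; the lifted end
    is one past the assembly coordinate of the last aligned reference base
    before ``ann.end``. Deletions at the gene boundaries therefore shrink the
    interval. Raises :class:`GeneAbsentError` when no gene base survives.

    Origin-wrapping genes are lifted piecewise over ``[start, L)`` and
    ``[0, end)`` and stay flagged as wrapping.
    """
    aligned_at, _ = _ref_to_qry_maps(alignment)
    L = len(aligned_at)
    if ann.start >= L or ann.end > L:
        raise ValueError(f"gene {ann.gene!r} outside reference covered by alignment")

    def lift_range(r0: int, r1: int) -> tuple[int, int] | None:
        hits = [aligned_at[r] for r in range(r0, r1) if aligned_at[r] >= 0]
        if not hits:
            return None
        return hits[0], hits[-1] + 1

    if not ann.wraps_origin:
        lifted = lift_range(ann.start, ann.end)
        if lifted is None:
            raise GeneAbsentError(f"gene {ann.gene!r} fully deleted in assembly")
        return GeneAnnotation(
            gene=ann.gene, kind=ann.kind, start=lifted[0], end=lifted[1],
            strand=ann.strand, wraps_origin=False, truncated_stop=ann.truncated_stop,
        )

    head = lift_range(ann.start, L)
    tail = lift_range(0, ann.end)
    if head is None and tail is None:
        raise GeneAbsentError(f"gene {ann.gene!r} fully deleted in assembly")
    qlen = len(alignment.qry_seq)
    start = head[0] if head is not None else 0
    end = tail[1] if tail is not None else qlen
    return GeneAnnotation(
        gene=ann.gene, kind=ann.kind, start=start, end=end, strand=ann.strand,
        wraps_origin=True, truncated_stop=ann.truncated_stop,
    )


def translate(cds: str, code: GeneticCode, strand: str = "+") -> str:
    """Translate a coding sequence; ``strand='-'`` reverse-complements first.

    ``len(cds) // 3`` codons are translated; 1-2 trailing bases are ignored
    (incomplete terminal stop codons are common in mitogenomes). Codons
    containing N (or any non-ACGT symbol) render 'X', never '*'.
    """
    s = cds.upper()
    if strand == "-":
        s = s.translate(_COMPLEMENT)[::-1]
    protein = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        protein.append(code.table.get(codon, "X"))
    return "".join(protein)


def count_internal_stops(
    assembly: CircularSeq,
    lifted: GeneAnnotation,
    code: GeneticCode,
    ref_length: int | None = None,
) -> OrfReport:
    """ORF report for one lifted protein-coding gene on the assembly.

    Internal stops exclude the final codon position (the legitimate
    terminator); frame_intact means the lifted length is divisible by 3.
    """
    if lifted.kind is not GeneKind.PCG:
        raise ValueError(f"gene {lifted.gene!r} is not a PCG")
    cds = lifted.extract(assembly)
    protein = translate(cds, code)  # extract() already applied strand
    internal = protein[:-1] if protein else ""
    n_stops = internal.count("*")
    length = lifted.length(len(assembly))
    return OrfReport(
        gene=lifted.gene,
        lifted_start=lifted.start,
        lifted_end=lifted.end,
        frame_intact=(length % 3 == 0),
        internal_stops=n_stops,
        length_delta=(length - ref_length) if ref_length is not None else None,
    )


def orf_reports(
    assembly: CircularSeq,
    alignment: PairwiseAlignment,
    ref_annotations: list[GeneAnnotation],
    code: GeneticCode | None = None,
    ref_length: int | None = None,
) -> list[OrfReport]:
    """Lift every PCG and report its ORF integrity; absent genes are flagged."""
    code = code or invertebrate_mito_code()
    reports = []
    for ann in ref_annotations:
        if ann.kind is not GeneKind.PCG:
            continue
        rlen = ann.length(ref_length) if ref_length is not None else None
        try:
            lifted = liftover(ann, alignment)
        except GeneAbsentError:
            reports.append(
                OrfReport(gene=ann.gene, lifted_start=-1, lifted_end=-1,
                          frame_intact=False, internal_stops=None,
                          length_delta=None, gene_absent=True)
            )
            continue
        reports.append(count_internal_stops(assembly, lifted, code, ref_length=rlen))
    return reports


def orf_reports_to_tsv(reports: list[OrfReport], path) -> None:
    """Export per-gene ORF reports (coordinates 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("gene\tstart\tend\tframe_intact\tinternal_stops\tlength_delta\tgene_absent\n")
        for r in reports:
            fh.write(
                f"{r.gene}\t{r.lifted_start + 1}\t{r.lifted_end}\t{r.frame_intact}\t"
                f"{'.' if r.internal_stops is None else r.internal_stops}\t"
                f"{'.' if r.length_delta is None else r.length_delta}\t{r.gene_absent}\n"
            )
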