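"""Domain types and readers/writers for sequences, annotations, and reports.

Internal coordinate convention is 0-based, half-open everywhere; exported
tables use 1-based inclusive coordinates. Genes that span the origin of the
circular molecule are kept as a single interval with ``wraps_origin=True``
rather than being split, so downstream ORF checks see one gene.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GeneKind(enum.Enum):
    """Feature classes of a metazoan mitogenome."""

    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CR = "CR"


@dataclass(frozen=True)
class CircularSeq:
    """A DNA sequence with a circularity flag; the unit being benchmarked.

    ``seq`` is stored uppercase over {A, C, G, T, N}. N is legal at load;
    how N sites are treated is decided per operation downstream.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"record {self.id!r}: illegal character {self.seq[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def rotated(self, offset: int) -> "CircularSeq":
        """Rotation moving position ``offset`` to the start (circular only)."""
        if not self.circular and offset % len(self.seq) != 0:
            raise ValueError(f"cannot rotate non-circular sequence {self.id!r}")
        off = offset % len(self.seq)
        return replace(self, seq=self.seq[off:] + self.seq[:off])

    def reverse_complement(self) -> "CircularSeq":
        return replace(self, seq=self.seq.translate(_COMPLEMENT)[::-1])


@dataclass(frozen=True)
class GeneAnnotation:
    """Typed gene interval on a CircularSeq (0-based, half-open).

    For genes spanning the origin, ``wraps_origin=True`` and ``end < start``;
    the gene covers ``[start, L) + [0, end)``. Mitogenome protein-coding genes
    may end on an incomplete stop codon (T/TA completed by polyadenylation),
    flagged with ``truncated_stop``.
    """

    gene: str
    kind: GeneKind
    start: int
    end: int
    strand: str
    wraps_origin: bool = False
    truncated_stop: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene!r}: strand must be '+' or '-'")
        if self.start < 0 or self.end < 0:
            raise ValueError(f"gene {self.gene!r}: negative coordinate")
        if not self.wraps_origin and self.end <= self.start:
            raise ValueError(
                f"gene {self.gene!r}: end {self.end} <= start {self.start} "
                "without wraps_origin"
            )

    def length(self, seq_length: int) -> int:
        if self.wraps_origin:
            return (seq_length - self.start) + self.end
        return self.end - self.start

    def validate_on(self, seq: CircularSeq) -> None:
        L = len(seq)
        if self.start >= L or self.end > L:
            raise ValueError(
                f"gene {self.gene!r}: interval [{self.start}, {self.end}) "
                f"exceeds sequence length {L}"
            )
        if self.wraps_origin and not seq.circular:
            raise ValueError(f"gene {self.gene!r} wraps origin of a linear sequence")

    def extract(self, seq: CircularSeq) -> str:
        """Gene sequence in reading orientation (reverse-complemented for −)."""
        if self.wraps_origin:
            s = seq.seq[self.start:] + seq.seq[: self.end]
        else:
            s = seq.seq[self.start : self.end]
        if self.strand == "-":
            s = s.translate(_COMPLEMENT)[::-1]
        return s


@dataclass
class AssemblyRecord:
    """A candidate assembly plus its pipeline metadata.

    Coverage is reported metadata passed through verbatim; it is never
    computed here.
    """

    seq: CircularSeq
    pipeline_label: str
    reported_coverage: float | None = None
    polished: bool = False

    def __post_init__(self) -> None:
        if not self.pipeline_label:
            raise ValueError("pipeline_label must be non-empty")
        if self.reported_coverage is not None and self.reported_coverage < 0:
            raise ValueError("reported_coverage must be >= 0")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, circular: bool = False) -> list[CircularSeq]:
    """Read a (multi-)FASTA file into CircularSeq records.

    Circularity is taken from a ``circular=true`` token in the header if
    present, otherwise from the ``circular`` argument.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        circ = circular
        for tok in tokens[1:]:
            if tok.lower() in ("circular=true", "circular=false"):
                circ = tok.lower().endswith("true")
        records.append(CircularSeq(id=rec.id, seq=str(rec.seq), circular=circ))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Sequence[CircularSeq], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id} circular={'true' if s.circular else 'false'}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations (GFF3 / BED)

_GFF_TYPE_TO_KIND = {
    "cds": GeneKind.PCG,
    "gene": GeneKind.PCG,
    "protein_coding_gene": GeneKind.PCG,
    "pcg": GeneKind.PCG,
    "trna": GeneKind.TRNA,
    "trna_gene": GeneKind.TRNA,
    "rrna": GeneKind.RRNA,
    "rrna_gene": GeneKind.RRNA,
    "d_loop": GeneKind.CR,
    "d-loop": GeneKind.CR,
    "control_region": GeneKind.CR,
    "cr": GeneKind.CR,
}


def _kind_from_name(name: str) -> GeneKind:
    low = name.lower()
    if low.startswith("trn"):
        return GeneKind.TRNA
    if low.startswith("rrn") or "rrna" in low:
        return GeneKind.RRNA
    if low in ("cr", "d-loop", "d_loop", "control_region"):
        return GeneKind.CR
    return GeneKind.PCG


def _normalize_interval(
    gene: str, start0: int, end: int, L: int, wraps_hint: bool
) -> tuple[int, int, bool]:
    """Map possibly origin-spanning coordinates to internal convention.

    An end beyond the sequence length denotes a gene running through the
    origin of the circle; it is normalized to ``end - L`` with
    ``wraps_origin=True``.
    """
    wraps = wraps_hint
    if end > L:
        wraps = True
        end -= L
        if end > start0:
            raise ValueError(f"gene {gene!r}: wrapped interval longer than sequence")
    elif start0 >= L:
        raise ValueError(f"gene {gene!r}: start {start0} beyond sequence length {L}")
    if not wraps and end > L:
        raise ValueError(
            f"gene {gene!r}: interval exceeds sequence length {L} without wraps_origin"
        )
    return start0, end, wraps


def _parse_gff3(path: Path, seq: CircularSeq) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    anns = []
    for feat in db.all_features(order_by=("start",)):
        attrs = feat.attributes
        name = (attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or [feat.id])[0]
        kind_token = (attrs.get("gene_kind") or [feat.featuretype])[0]
        kind = _GFF_TYPE_TO_KIND.get(kind_token.lower())
        if kind is None:
            kind = _GFF_TYPE_TO_KIND.get(feat.featuretype.lower())
        if kind is None:
            raise ValueError(f"unknown feature kind {kind_token!r} for {name!r}")
        wraps_hint = (attrs.get("wraps_origin") or ["false"])[0].lower() == "true"
        truncated = (attrs.get("truncated_stop") or ["false"])[0].lower() == "true"
        start0, end, wraps = _normalize_interval(
            name, feat.start - 1, feat.end, len(seq), wraps_hint
        )
        anns.append(
            GeneAnnotation(
                gene=name, kind=kind, start=start0, end=end,
                strand=feat.strand if feat.strand in "+-" else "+",
                wraps_origin=wraps, truncated_stop=truncated,
            )
        )
    return anns


def _parse_bed(path: Path, seq: CircularSeq) -> list[GeneAnnotation]:
    anns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            start0, end = int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"feature{lineno}"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            if "|" in name:
                name, kind_token = name.split("|", 1)
                kind = _GFF_TYPE_TO_KIND.get(kind_token.lower())
                if kind is None:
                    raise ValueError(f"unknown feature kind {kind_token!r} for {name!r}")
            else:
                kind = _kind_from_name(name)
            start0, end, wraps = _normalize_interval(name, start0, end, len(seq), False)
            anns.append(
                GeneAnnotation(gene=name, kind=kind, start=start0, end=end,
                               strand=strand, wraps_origin=wraps)
            )
    return anns


def read_annotation(path: str | Path, seq: CircularSeq) -> list[GeneAnnotation]:
    """Read gene annotations (GFF3 or 6-column BED) for ``seq``.

    GFF3 coordinates are 1-based inclusive, BED 0-based half-open; both are
    normalized to the internal 0-based half-open convention. Intervals with an
    end beyond the sequence length are interpreted as wrapping the origin.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        anns = _parse_gff3(path, seq)
    elif suffix == ".bed":
        anns = _parse_bed(path, seq)
    else:
        with open(path) as fh:
            first = fh.readline()
        anns = (
            _parse_gff3(path, seq)
            if first.startswith("##gff") or first.count("\t") >= 7
            else _parse_bed(path, seq)
        )
    for ann in anns:
        ann.validate_on(seq)
    return anns


def write_annotation(
    anns: Iterable[GeneAnnotation], path: str | Path, seq: CircularSeq
) -> None:
    """Write annotations as GFF3 (1-based inclusive; wrapped genes get end > L)."""
    kind_to_type = {
        GeneKind.PCG: "CDS",
        GeneKind.TRNA: "tRNA",
        GeneKind.RRNA: "rRNA",
        GeneKind.CR: "D_loop",
    }
    L = len(seq)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seq.id} 1 {L}\n")
        for ann in anns:
            end = ann.end + L if ann.wraps_origin else ann.end
            attrs = f"ID={ann.gene};Name={ann.gene};gene_kind={ann.kind.value}"
            if ann.wraps_origin:
                attrs += ";wraps_origin=true"
            if ann.truncated_stop:
                attrs += ";truncated_stop=true"
            fh.write(
                f"{seq.id}\tmitobench\t{kind_to_type[ann.kind]}\t{ann.start + 1}\t"
                f"{end}\t.\t{ann.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Reports


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Write an AccuracyReport (or list of them) or an ErrorProfile.

    Column order is fixed: pipeline_label, contigs, length, coverage, p_dist,
    errors, then one column per error category in the fixed taxonomy order.
    """
    import pandas as pd

    from mitobench.error_taxonomy import CATEGORIES, ErrorProfile

    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")

    if isinstance(report, ErrorProfile):
        rows = [dict(report.counts, total=report.total)]
        columns = list(CATEGORIES) + ["total"]
    else:
        reports = report if isinstance(report, (list, tuple)) else [report]
        rows = [r.to_row() for r in reports]
        columns = list(rows[0].keys())

    df = pd.DataFrame(rows, columns=columns)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    else:
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2, default=str)
            fh.write("\n")
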