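"""Benchmark orchestration: one accuracy report per candidate assembly.

For each assembly the workflow is: orientation normalization (rotation +
strand) onto the reference frame, global affine-gap alignment, left
justification, p-distance, error-event extraction and classification, and
annotation liftover with internal-stop counting for every protein-coding
gene. Coverage is echoed from metadata, never computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from mitobench.annotation_orf import (
    GeneticCode,
    OrfReport,
    invertebrate_mito_code,
    orf_reports,
    orf_reports_to_tsv,
)
from mitobench.circular_alignment import (
    DEFAULT_SCORING,
    Orientation,
    PairwiseAlignment,
    Scoring,
    global_align,
    left_justify,
    normalize_orientation,
    p_distance,
)
from mitobench.core_io import AssemblyRecord, CircularSeq, GeneAnnotation
from mitobench.error_taxonomy import (
    CATEGORIES,
    ErrorEvent,
    ErrorProfile,
    TaxonomyConfig,
    DEFAULT_TAXONOMY,
    classify_events,
    events_to_tsv,
    extract_events,
    profile,
)


@dataclass(frozen=True)
class AccuracyReport:
    """One benchmark table row for one assembly.

    ``contigs`` reports the assembly topology (circular/linear/absent);
    ``coverage`` is reported metadata passed through; ``errors`` equals the
    profile total; ``incomplete`` flags assemblies shorter than half the
    reference, which are still reported.
    """

    pipeline_label: str
    contigs: str
    length: int
    coverage: float | None
    p_dist: float
    errors: int
    profile: ErrorProfile
    genes_with_internal_stops: int
    total_internal_stops: int
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.errors != self.profile.total:
            raise ValueError("errors must equal profile total")

    def to_row(self) -> dict:
        row = {
            "pipeline_label": self.pipeline_label,
            "contigs": self.contigs,
            "length": self.length,
            "coverage": "" if self.coverage is None else self.coverage,
            "p_dist": self.p_dist,
            "errors": self.errors,
        }
        row.update({c: self.profile[c] for c in CATEGORIES})
        row["genes_with_internal_stops"] = self.genes_with_internal_stops
        row["total_internal_stops"] = self.total_internal_stops
        row["incomplete"] = self.incomplete
        return row


@dataclass(frozen=True)
class BenchmarkResult:
    """Full per-assembly output: the table row plus its supporting detail."""

    report: AccuracyReport
    orientation: Orientation
    alignment: PairwiseAlignment
    events: list[ErrorEvent]
    orf: list[OrfReport]


def benchmark_assembly(
    reference: CircularSeq,
    ref_annotations: list[GeneAnnotation],
    assembly: AssemblyRecord,
    scoring: Scoring = DEFAULT_SCORING,
    taxonomy: TaxonomyConfig = DEFAULT_TAXONOMY,
    code: GeneticCode | None = None,
    anchor_k: int = 31,
) -> BenchmarkResult:
    """Benchmark one assembly against the trusted reference."""
    code = code or invertebrate_mito_code()
    normalized, orientation = normalize_orientation(assembly.seq, reference, k=anchor_k)
    alignment = left_justify(global_align(reference, normalized, scoring))
    p = p_distance(alignment)
    events = classify_events(extract_events(alignment), reference, taxonomy)
    prof = profile(events)
    orfs = orf_reports(normalized, alignment, ref_annotations, code,
                       ref_length=len(reference))
    stops = [r.internal_stops for r in orfs if r.internal_stops is not None]
    report = AccuracyReport(
        pipeline_label=assembly.pipeline_label,
        contigs="circular" if assembly.seq.circular else "linear",
        length=len(assembly.seq),
        coverage=assembly.reported_coverage,
        p_dist=p,
        errors=prof.total,
        profile=prof,
        genes_with_internal_stops=sum(1 for s in stops if s > 0),
        total_internal_stops=sum(stops),
        incomplete=len(assembly.seq) < 0.5 * len(reference),
    )
    return BenchmarkResult(report=report, orientation=orientation,
                           alignment=alignment, events=events, orf=orfs)


def benchmark_panel(
    reference: CircularSeq,
    ref_annotations: list[GeneAnnotation],
    assemblies: list[AssemblyRecord],
    outdir: str | Path | None = None,
    **kwargs,
) -> list[BenchmarkResult]:
    """Benchmark each assembly independently; optionally write report files.

    When ``outdir`` is given, writes ``report.tsv`` (fixed column order), one
    events TSV and one per-gene ORF TSV per assembly, and a JSON-lines log of
    orientation decisions.
    """
    from mitobench.core_io import write_report

    results = [benchmark_assembly(reference, ref_annotations, a, **kwargs)
               for a in assemblies]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report([r.report for r in results], outdir / "report.tsv", "tsv")
        write_report([r.report for r in results], outdir / "report.json", "json")
        with open(outdir / "log.jsonl", "w") as log:
            for r in results:
                label = r.report.pipeline_label
                events_to_tsv(r.events, outdir / f"events_{label}.tsv")
                orf_reports_to_tsv(r.orf, outdir / f"orf_{label}.tsv")
                log.write(json.dumps({
                    "assembly": label,
                    "orientation": r.orientation.to_json_dict(),
                    "p_dist": r.report.p_dist,
                    "errors": r.report.errors,
                }) + "\n")
    return results
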