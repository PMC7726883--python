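"""Synthetic circular mitogenomes and assemblies with ledgered error profiles.

The generator emulates the architecture of a pancrustacean mitochondrial
genome: a circular molecule (default 15,739 bp) carrying 13 protein-coding
genes that are valid ORFs under the invertebrate mitochondrial code, 22 tRNA
and 2 rRNA genes (random-sequence placeholders; ORF integrity is only defined
for PCGs), one control region (default 801 bp), AT-rich base composition
(default GC 0.40) and seeded homopolymer runs — the sequence context in which
nanopore assemblies make most of their errors.

``inject_errors`` produces an assembly copy carrying exact, ledgered counts of
each error category. Under ``context_policy='unambiguous'`` sites are chosen
so that alignment + classification must recover the ledger exactly: events
are >= 10 bp apart, homopolymer events sit in runs long enough to classify
uniquely, and non-homopolymer events avoid homopolymer context. The ledger is
the ground truth oracle for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mitobench.core_io import AssemblyRecord, CircularSeq, GeneAnnotation, GeneKind
from mitobench.error_taxonomy import CATEGORIES, ErrorProfile

_BASES = "ACGT"
# codon-aligned homopolymer seeds that are stop-free under table 5
_SAFE_HP_CODON_PAIRS = {"A": "AAAAAA", "C": "CCCCCC", "G": "GGGGGG", "T": "TTTTTT"}


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic mitogenome.

    hp_enrichment is the expected number of seeded homopolymer runs of
    length >= 5 per kb (on top of runs arising by chance); 2.0/kb gives a
    run density comparable to AT-rich invertebrate mitogenomes.
    """

    length: int = 15_739
    n_pcg: int = 13
    n_trna: int = 22
    n_rrna: int = 2
    control_region_len: int = 801
    gc: float = 0.40
    hp_enrichment: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if min(self.length, self.n_pcg) < 0 or min(self.n_trna, self.n_rrna) < 0:
            raise ValueError("counts must be non-negative")
        if self.hp_enrichment < 0:
            raise ValueError("hp_enrichment must be >= 0")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join(_BASES[i] for i in idx)


def _random_orf(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG start, stop-free body, TAA terminator (table 5 stops: TAA/TAG)."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3, gc)
        if c not in ("TAA", "TAG"):
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def simulate_mitogenome(spec: GenomeSpec) -> tuple[CircularSeq, list[GeneAnnotation]]:
    """Generate a circular mitogenome and its annotation, deterministically.

    PCGs are valid ORFs (start codon, no internal stop, terminal stop) under
    translation table 5. At least 4 PCGs, 8 tRNAs and both rRNAs go on the
    minus strand when available, mirroring the typical asymmetric strand
    usage of pancrustacean mitogenomes. Gene sizes follow realistic
    mitochondrial proportions (tRNA ~66 bp, rRNA ~850/1330 bp) with PCGs
    absorbing the remaining length.
    """
    rng = np.random.default_rng(spec.seed)
    trna_len = 66
    rrna_lens = [850, 1330][: spec.n_rrna] + [1000] * max(0, spec.n_rrna - 2)
    spacer = 2
    n_features = spec.n_pcg + spec.n_trna + spec.n_rrna + 1
    fixed = (
        spec.control_region_len
        + spec.n_trna * trna_len
        + sum(rrna_lens)
        + spacer * n_features
    )
    pcg_budget = spec.length - fixed
    if spec.n_pcg > 0 and pcg_budget < 150 * spec.n_pcg:
        raise ValueError("genes cannot fit: increase length or reduce gene counts")

    # Split the PCG budget into codon-multiple gene lengths (>= 150 nt each).
    if spec.n_pcg:
        weights = rng.uniform(0.5, 1.5, size=spec.n_pcg)
        raw = weights / weights.sum() * pcg_budget
        pcg_lens = [max(150, int(x // 3) * 3) for x in raw]
    else:
        pcg_lens = []

    # Feature order: interleave tRNAs between PCGs/rRNAs, control region last.
    features: list[tuple[str, GeneKind, int, str]] = []
    minus_pcg = min(4, spec.n_pcg)
    minus_trna = min(8, spec.n_trna)
    for i in range(spec.n_pcg):
        strand = "-" if i < minus_pcg else "+"
        features.append((f"pcg{i + 1}", GeneKind.PCG, pcg_lens[i], strand))
    for i in range(spec.n_rrna):
        features.append((f"rrn{'SL'[i] if i < 2 else i}", GeneKind.RRNA, rrna_lens[i], "-"))
    for i in range(spec.n_trna):
        strand = "-" if i < minus_trna else "+"
        features.append((f"trn{i + 1}", GeneKind.TRNA, trna_len, strand))
    order = rng.permutation(len(features))
    features = [features[i] for i in order]
    features.append(("CR", GeneKind.CR, spec.control_region_len, "+"))

    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 0
    for name, kind, length, strand in features:
        parts.append(_random_seq(rng, spacer, spec.gc))
        pos += spacer
        if kind is GeneKind.PCG:
            seq = _random_orf(rng, length // 3, spec.gc)
            if strand == "-":
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        else:
            seq = _random_seq(rng, length, spec.gc)
        parts.append(seq)
        annotations.append(
            GeneAnnotation(gene=name, kind=kind, start=pos, end=pos + len(seq), strand=strand)
        )
        pos += len(seq)

    genome = list("".join(parts))
    if len(genome) < spec.length:  # pad tail with intergenic sequence
        genome += list(_random_seq(rng, spec.length - len(genome), spec.gc))
    genome = genome[: spec.length]

    _seed_homopolymers(rng, genome, annotations, spec)
    seq = CircularSeq(id=f"synthetic_mitogenome_seed{spec.seed}",
                      seq="".join(genome), circular=True)
    return seq, annotations


def _seed_homopolymers(
    rng: np.random.Generator,
    genome: list[str],
    annotations: list[GeneAnnotation],
    spec: GenomeSpec,
) -> None:
    """Write homopolymer runs into the genome without breaking ORFs.

    Inside PCGs the run is a codon-aligned 6-mer of one base (AAA AAA etc.,
    all stop-free under table 5 on both strands); elsewhere runs of 5-8 bases
    are written anywhere.
    """
    n_runs = int(round(spec.hp_enrichment * spec.length / 1000))
    pcgs = [a for a in annotations if a.kind is GeneKind.PCG]
    for _ in range(n_runs):
        base = _BASES[rng.integers(4)]
        if pcgs and rng.random() < 0.5:
            g = pcgs[rng.integers(len(pcgs))]
            n_codons = (g.end - g.start) // 3
            if n_codons < 6:
                continue
            ci = int(rng.integers(1, n_codons - 3))  # keep start & stop codons
            s = g.start + 3 * ci
            genome[s : s + 6] = list(_SAFE_HP_CODON_PAIRS[base])
        else:
            run_len = int(rng.integers(5, 9))
            # avoid clobbering PCG start/stop codons: place outside PCGs
            for _attempt in range(20):
                s = int(rng.integers(0, spec.length - run_len))
                if not any(a.start <= s < a.end or a.start < s + run_len <= a.end
                           for a in pcgs):
                    genome[s : s + run_len] = [base] * run_len
                    break


# ---------------------------------------------------------------------------
# Error injection


@dataclass(frozen=True)
class InjectionSpec:
    """Requested per-category error counts plus site-selection policy.

    ``unambiguous`` placement guarantees exact ledger recovery by the
    aligner + classifier; ``anywhere`` only enforces per-category validity
    and is meant for stress testing.
    """

    counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    context_policy: str = "unambiguous"

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative requested count")
        if self.context_policy not in ("unambiguous", "anywhere"):
            raise ValueError(f"unknown context_policy {self.context_policy!r}")


def nanopore_like_preset(seed: int = 0, scale: float = 1.0) -> InjectionSpec:
    """Error mix echoing an unpolished nanopore assembly (~277 events/16 kb).

    Single homopolymer deletions dominate, followed by single homopolymer
    insertions; doubles and single insertions are moderate; triples, single
    deletions, short insertions and substitutions are less common; longer
    homopolymer insertions and short deletions are rare.
    """
    base = {
        "hp_del_1": 150, "hp_ins_1": 45, "hp_del_2": 20, "hp_ins_2": 15,
        "single_insertion": 15, "hp_del_3": 8, "single_deletion": 8,
        "short_insertion": 6, "substitution": 5, "hp_ins_3": 2,
        "hp_ins_4": 1, "hp_ins_5": 1, "short_deletion": 1,
    }
    counts = {k: int(round(v * scale)) for k, v in base.items()}
    return InjectionSpec(counts=counts, seed=seed)


def polished_like_preset(seed: int = 0) -> InjectionSpec:
    """Error mix echoing a consensus-polished assembly (~50 events/16 kb)."""
    return InjectionSpec(
        counts={"hp_del_1": 28, "hp_ins_1": 10, "hp_del_2": 4, "hp_ins_2": 2,
                "single_insertion": 3, "single_deletion": 2, "substitution": 1},
        seed=seed,
    )


@dataclass(frozen=True)
class LedgerEntry:
    ref_pos: int
    category: str
    ref_allele: str
    alt_allele: str


@dataclass(frozen=True)
class TruthLedger:
    """Ground-truth record of every injected event, in reference coordinates."""

    entries: tuple[LedgerEntry, ...]

    @property
    def profile(self) -> ErrorProfile:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.category] = counts.get(e.category, 0) + 1
        return ErrorProfile(counts=counts)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ref_pos\tcategory\tref_allele\talt_allele\n")
            for e in sorted(self.entries, key=lambda x: x.ref_pos):
                fh.write(f"{e.ref_pos + 1}\t{e.category}\t{e.ref_allele or '.'}\t"
                         f"{e.alt_allele or '.'}\n")


def _homopolymer_runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal runs as (start, length, base), linear scan (no origin wrap)."""
    runs = []
    i = 0
    L = len(seq)
    while i < L:
        j = i
        while j + 1 < L and seq[j + 1] == seq[i]:
            j += 1
        runs.append((i, j - i + 1, seq[i]))
        i = j + 1
    return runs


def _category_sites(seq: str, category: str, rng: np.random.Generator,
                    unambiguous: bool) -> list[LedgerEntry]:
    """All candidate ledger entries for one category, shuffled."""
    L = len(seq)
    margin = 50  # keep clear of the linearization ends
    runs = [r for r in _homopolymer_runs(seq) if margin <= r[0] and r[0] + r[1] <= L - margin]
    out: list[LedgerEntry] = []

    def run_at(pos: int) -> int:
        b = seq[pos]
        i = pos
        while i > 0 and seq[i - 1] == b:
            i -= 1
        j = pos
        while j + 1 < L and seq[j + 1] == b:
            j += 1
        return j - i + 1

    if category.startswith("hp_del_"):
        d = int(category[-1])
        min_run = max(4, d + 1) if unambiguous else max(3, d)
        for start, length, base in runs:
            if length >= min_run:
                out.append(LedgerEntry(start, category, base * d, ""))
    elif category.startswith("hp_ins_"):
        i = int(category[-1])
        for start, length, base in runs:
            if length >= 3:
                out.append(LedgerEntry(start, category, "", base * i))
    elif category == "substitution":
        for pos in range(margin, L - margin):
            alts = [b for b in _BASES if b != seq[pos]]
            if unambiguous:
                # keep the substituted base off both neighbours so the
                # mismatch cannot be re-explained as an indel pair shift
                alts = [b for b in alts if b != seq[pos - 1] and b != seq[pos + 1]]
            if alts:
                out.append(LedgerEntry(pos, category, seq[pos],
                                       alts[int(rng.integers(len(alts)))]))
    elif category == "single_insertion":
        for pos in range(margin, L - margin):
            alts = [b for b in _BASES
                    if _flank_ok(seq, pos, b, unambiguous)]
            if alts:
                out.append(LedgerEntry(pos, category, "",
                                       alts[int(rng.integers(len(alts)))]))
    elif category == "short_insertion":
        for pos in range(margin, L - margin):
            a = _BASES[int(rng.integers(4))]
            b = rng.choice([x for x in _BASES if x != a])
            ins = a + b
            if not unambiguous or (seq[pos - 1] not in ins and seq[pos] not in ins):
                out.append(LedgerEntry(pos, category, "", ins))
    elif category == "single_deletion":
        for pos in range(margin, L - margin):
            if run_at(pos) == 1:
                out.append(LedgerEntry(pos, category, seq[pos], ""))
    elif category == "short_deletion":
        for pos in range(margin, L - margin - 2):
            window = seq[pos : pos + 2]
            if window[0] == window[1]:
                continue
            # a deletion gap left-shifts while seq[pos-1] == seq[pos+1]; block it
            if unambiguous and (seq[pos - 1] == window[1]
                                or run_at(pos) >= 3 or run_at(pos + 1) >= 3):
                continue
            out.append(LedgerEntry(pos, category, window, ""))
    elif category == "long_indel_other":
        for pos in range(margin, L - margin - 8):
            window = seq[pos : pos + 7]
            if len(set(window)) >= 2 and (not unambiguous
                                          or seq[pos - 1] != window[-1]):
                out.append(LedgerEntry(pos, category, window, ""))
    else:  # pragma: no cover - CATEGORIES is closed
        raise ValueError(f"no injector for category {category!r}")

    rng.shuffle(out)
    return out


def _flank_ok(seq: str, pos: int, base: str, unambiguous: bool) -> bool:
    """Valid context for a non-homopolymer single insertion of ``base`` at pos."""
    if unambiguous:
        return seq[pos - 1] != base and seq[pos] != base
    # flanking runs of `base` must stay below the homopolymer threshold
    left = 0
    i = pos - 1
    while i >= 0 and seq[i] == base:
        left += 1
        i -= 1
    right = 0
    i = pos
    while i < len(seq) and seq[i] == base:
        right += 1
        i += 1
    return max(left, right) < 3


def _event_span(e: LedgerEntry, seq: str) -> tuple[int, int]:
    """Reference interval an event occupies for spacing purposes.

    Homopolymer events block their entire run: two events in one run would
    merge into a single alignment gap and break ledger recovery.
    """
    if e.category.startswith("hp_"):
        b = (e.ref_allele or e.alt_allele)[0]
        i = e.ref_pos
        while i > 0 and seq[i - 1] == b:
            i -= 1
        j = e.ref_pos
        while j < len(seq) and seq[j] == b:
            j += 1
        return i, j
    return e.ref_pos, e.ref_pos + max(len(e.ref_allele), 1)


def inject_errors(
    genome: CircularSeq, spec: InjectionSpec
) -> tuple[CircularSeq, TruthLedger]:
    """Mutate a copy of ``genome`` with exactly the requested error counts.

    Sites are drawn per category, then accepted greedily under a >= 10 bp
    separation between events (and, for homopolymer events, one event per
    run). Raises naming the starving category when the sequence lacks enough
    valid contexts.
    """
    rng = np.random.default_rng(spec.seed)
    seq = genome.seq
    unamb = spec.context_policy == "unambiguous"
    min_gap = 10

    chosen: list[LedgerEntry] = []
    occupied: list[tuple[int, int]] = []

    def far_enough(span: tuple[int, int]) -> bool:
        return all(span[1] + min_gap <= s or e + min_gap <= span[0]
                   for s, e in occupied)

    # homopolymer categories first (scarcer contexts), then the rest
    order = sorted((c for c, n in spec.counts.items() if n > 0),
                   key=lambda c: (not c.startswith("hp_"), c))
    for category in order:
        needed = spec.counts[category]
        placed = 0
        for cand in _category_sites(seq, category, rng, unamb):
            if placed == needed:
                break
            span = _event_span(cand, seq)
            if far_enough(span):
                chosen.append(cand)
                occupied.append(span)
                placed += 1
        if placed < needed:
            raise ValueError(
                f"insufficient valid contexts for category {category!r}: "
                f"needed {needed}, found {placed}"
            )

    # apply right-to-left so reference coordinates stay valid
    out = list(seq)
    for e in sorted(chosen, key=lambda x: -x.ref_pos):
        if e.ref_allele and e.alt_allele:  # substitution
            out[e.ref_pos] = e.alt_allele
        elif e.ref_allele:  # deletion
            del out[e.ref_pos : e.ref_pos + len(e.ref_allele)]
        else:  # insertion
            out[e.ref_pos:e.ref_pos] = list(e.alt_allele)

    mutated = replace(genome, id=genome.id + "_mut", seq="".join(out))
    return mutated, TruthLedger(entries=tuple(sorted(chosen, key=lambda x: x.ref_pos)))


def simulate_assembly_panel(
    genome: CircularSeq,
    presets: list[tuple[str, InjectionSpec]],
    rotate: bool = True,
) -> list[tuple[AssemblyRecord, TruthLedger]]:
    """One mutated assembly copy per preset, each with its truth ledger.

    Copies are rotated and/or reverse-complemented by a seed-driven choice to
    exercise orientation normalization downstream.
    """
    if not presets:
        raise ValueError("presets must be non-empty")
    out = []
    for label, ispec in presets:
        mutated, ledger = inject_errors(genome, ispec)
        rng = np.random.default_rng((ispec.seed, 0xA55))
        if rotate and genome.circular:
            if rng.random() < 0.5:
                mutated = mutated.reverse_complement()
            mutated = mutated.rotated(int(rng.integers(0, len(mutated))))
        mutated = replace(mutated, id=label)
        out.append((AssemblyRecord(seq=mutated, pipeline_label=label), ledger))
    return out
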