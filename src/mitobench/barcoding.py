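"""Barcode-panel preparation filters and nearest-neighbor identification.

Emulates the preparation of a cox1 barcoding panel: records containing
ambiguous 'N' bases are removed, the master alignment is sliced into the
standard barcoding windows (columns 1-500, 501-1000 and 1001-1539, 1-based
inclusive), and records with fewer than 250 non-gap bases in the window are
dropped. Identification is distance-based: the query is globally aligned to
each panel record and assigned the label of the minimum p-distance record.
This nearest-neighbor assignment is a deliberate stand-in for
maximum-likelihood tree clustering — the claim it tests (a query groups with
conspecific sequences and away from congeners) reduces to relative distance
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

from mitobench.circular_alignment import (
    DEFAULT_SCORING,
    Scoring,
    global_align,
    p_distance,
)
from mitobench.core_io import CircularSeq

#: 1-based inclusive column ranges of the barcoding windows.
WINDOWS: dict[str, tuple[int, int] | None] = {
    "w1": (1, 500),
    "w2": (501, 1000),
    "w3": (1001, 1539),
    "full": None,
}


@dataclass(frozen=True)
class FilterLog:
    """Per-filter casualty counts from panel preparation."""

    n_input: int
    n_removed_n: int
    n_removed_short: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_n - self.n_removed_short


@dataclass(frozen=True)
class BarcodePanel:
    """Window-sliced, filtered panel of (species label, aligned sequence)."""

    records: tuple[tuple[str, str], ...]
    window: str
    log: FilterLog

    @property
    def labels(self) -> set[str]:
        return {label for label, _ in self.records}


@dataclass(frozen=True)
class IdentificationResult:
    """Nearest-neighbor call with its safety margin.

    ``margin`` is the distance gap between the best record of the winning
    species and the best record of any other species; zero means a tie that
    was broken deterministically.
    """

    query_id: str
    best_label: str
    best_distance: float
    runner_up_label: str
    margin: float

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def read_panel_fasta(path) -> list[tuple[str, str]]:
    """Read a panel FASTA whose headers carry ``label=<species>`` tokens."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = rec.id
        for tok in rec.description.split():
            if tok.startswith("label="):
                label = tok[len("label="):]
        records.append((label, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no records in panel {path}")
    return records


def _impose_frame(records: list[tuple[str, str]],
                  scoring: Scoring = DEFAULT_SCORING) -> list[tuple[str, str]]:
    """Project raw (unaligned) records onto the coordinates of the longest one.

    Each record is globally aligned to the master; bases inserted relative to
    the master are dropped so every record has one character per master
    column. Already-aligned panels (equal lengths) pass through unchanged.
    """
    lengths = {len(s) for _, s in records}
    if len(lengths) == 1:
        return records
    master = max((s for _, s in records), key=len)
    out = []
    for label, seq in records:
        if len(seq) == len(master):
            out.append((label, seq))
            continue
        aln = global_align(
            CircularSeq(id="master", seq=master.replace("-", "") or master),
            CircularSeq(id="rec", seq=seq.replace("-", "")),
            scoring,
        )
        row = []
        for rc, qc in zip(aln.ref_row, aln.qry_row):
            if rc != "-":
                row.append(qc if qc != "-" else "-")
        out.append((label, "".join(row)))
    return out


def prepare_panel(
    records: list[tuple[str, str]],
    window: str = "full",
    min_len: int = 250,
    scoring: Scoring = DEFAULT_SCORING,
) -> BarcodePanel:
    """Apply the barcoding panel filters in order.

    1. remove records containing any N;
    2. slice the window columns on the master alignment;
    3. remove records with fewer than ``min_len`` non-gap bases in-window.

    Order-independent up to record order: permuting the input permutes the
    output without changing membership. Raises when nothing survives.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    records = [(label, seq.upper()) for label, seq in records]

    kept_n = [(label, seq) for label, seq in records if "N" not in seq]
    n_removed_n = len(records) - len(kept_n)

    framed = _impose_frame(kept_n, scoring) if kept_n else []
    bounds = WINDOWS[window]
    if bounds is not None:
        lo, hi = bounds[0] - 1, bounds[1]
        framed = [(label, seq[lo:hi]) for label, seq in framed]

    kept = [(label, seq) for label, seq in framed
            if len(seq) - seq.count("-") >= min_len]
    n_removed_short = len(framed) - len(kept)

    if not kept:
        raise ValueError("no records left after N/length filtering")
    return BarcodePanel(
        records=tuple(kept),
        window=window,
        log=FilterLog(n_input=len(records), n_removed_n=n_removed_n,
                      n_removed_short=n_removed_short),
    )


def identify(
    query: str,
    panel: BarcodePanel,
    query_id: str = "query",
    scoring: Scoring = DEFAULT_SCORING,
) -> IdentificationResult:
    """Nearest-neighbor species assignment by p-distance.

    The query is globally aligned to each panel record (gaps stripped first)
    and p-distance computed with pairwise deletion. Ties on the minimum are
    broken by species-level mean distance, then lexicographic label. Records
    with no comparable sites are skipped with a warning; if all are skipped,
    an error is raised.
    """
    import warnings

    if len(panel.labels) < 2:
        raise ValueError("panel must contain at least 2 distinct species labels")
    q = query.upper().replace("-", "")
    if not q:
        raise ValueError("empty query")

    dists: list[tuple[str, float]] = []
    for label, seq in panel.records:
        s = seq.replace("-", "")
        if not s:
            continue
        aln = global_align(CircularSeq(id="panel", seq=s),
                           CircularSeq(id=query_id, seq=q), scoring)
        try:
            dists.append((label, p_distance(aln)))
        except ValueError:
            warnings.warn(f"no comparable sites between {query_id!r} and a "
                          f"record of {label!r}; skipped")
    if not dists:
        raise ValueError("no panel record comparable to the query")

    best_per_label: dict[str, float] = {}
    sums: dict[str, list[float]] = {}
    for label, d in dists:
        best_per_label[label] = min(d, best_per_label.get(label, float("inf")))
        sums.setdefault(label, []).append(d)
    mean_per_label = {lb: sum(v) / len(v) for lb, v in sums.items()}

    ranked = sorted(best_per_label,
                    key=lambda lb: (best_per_label[lb], mean_per_label[lb], lb))
    best = ranked[0]
    runner_up = min((lb for lb in best_per_label if lb != best),
                    key=lambda lb: (best_per_label[lb], mean_per_label[lb], lb),
                    default=None)
    if runner_up is None:  # pragma: no cover - guarded by the 2-label check
        raise ValueError("panel collapsed to a single species after filtering")
    return IdentificationResult(
        query_id=query_id,
        best_label=best,
        best_distance=best_per_label[best],
        runner_up_label=runner_up,
        margin=best_per_label[runner_up] - best_per_label[best],
    )


def distance_matrix(panel: BarcodePanel, scoring: Scoring = DEFAULT_SCORING):
    """Square p-distance matrix over panel records (pandas DataFrame)."""
    import pandas as pd

    n = len(panel.records)
    ids = [f"{label}_{i}" for i, (label, _) in enumerate(panel.records)]
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a = panel.records[i][1].replace("-", "")
            b = panel.records[j][1].replace("-", "")
            aln = global_align(CircularSeq(id="a", seq=a),
                               CircularSeq(id="b", seq=b), scoring)
            d = p_distance(aln)
            mat[i][j] = mat[j][i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)
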