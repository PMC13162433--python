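"""Clone-identifier recovery from cell-tagged reads.

The extractor scans each read (both strands) for the fixed 3' vector-backbone
anchor, orientation-normalizes to vector sense, and reports the 15 nt of
barcode immediately 5' of the anchor — the suffix of the full semi-random
barcode.  Reads then pass a QC cascade, resolved in a fixed order:

``no_anchor`` → ``empty_vector`` (the bases adjacent to the anchor match the
configured empty-vector signature) → ``short`` (fewer than 15 nt of barcode
available) → ``pattern_fail`` (the 15-mer violates the terminal-segment repeat
pattern) → ``ok``.

Hits are collapsed per (cell, UMI) with majority consensus, UMIs are counted
per (cell, clone), and cells carrying two or more surviving clone identifiers
are removed as presumptive multiplets/multi-infections.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam

from merlin.barcode_design import (
    BarcodeBlueprint,
    DEFAULT_ANCHOR,
    default_blueprint,
    segment_matches,
)

#: Vector sequence found next to the anchor when no barcode insert is present.
#: Synthetic placeholder literal; configurable.
DEFAULT_EMPTY_VECTOR_SIGNATURE = "GGTACCCGGGAATTC"

CLONE_ID_LENGTH = 15

STATUSES = ("ok", "no_anchor", "empty_vector", "short", "pattern_fail")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TaggedRead:
    """A read annotated with its cell barcode (CB) and UMI (UB) tags."""

    read_id: str
    seq: str
    cell_tag: str
    umi: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("read sequence must be non-empty")
        if not self.cell_tag:
            raise ValueError("cell tag must be non-empty")


@dataclass(frozen=True)
class ExtractionHit:
    cell_tag: str
    umi: str
    status: str
    clone_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.clone_id is not None) != (self.status == "ok"):
            raise ValueError("clone_id present iff status == 'ok'")
        if self.clone_id is not None and len(self.clone_id) != CLONE_ID_LENGTH:
            raise ValueError("clone_id must be 15 nt")


@dataclass
class CellCloneTable:
    """Cell→clone assignments plus the QC report of the extraction run."""

    assignments: pd.DataFrame  # columns: cell_tag, clone_id, umi_support
    qc: dict = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)

    def qc_to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.qc, fh, indent=2, sort_keys=True)


def locate_anchor(
    seq: str, anchor: str = DEFAULT_ANCHOR, max_mismatch: int = 0
) -> Optional[tuple[int, str]]:
    """First anchor occurrence in ``seq`` or its reverse complement.

    Returns ``(offset, strand)`` with the offset in coordinates of the matched
    strand ('+' = as given, '-' = reverse complement), or ``None``.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    if max_mismatch >= len(anchor):
        raise ValueError("max_mismatch must be < anchor length")
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        if max_mismatch == 0:
            off = s.find(anchor)
            if off >= 0:
                return off, strand
        else:
            for off in range(len(s) - len(anchor) + 1):
                window = s[off : off + len(anchor)]
                mm = sum(a != b for a, b in zip(window, anchor))
                if mm <= max_mismatch:
                    return off, strand
    return None


def extract_clone_id(
    read: TaggedRead,
    bp: BarcodeBlueprint | None = None,
    anchor: str = DEFAULT_ANCHOR,
    empty_vector_signature: str = DEFAULT_EMPTY_VECTOR_SIGNATURE,
    max_mismatch: int = 0,
) -> ExtractionHit:
    """Apply the anchor scan and QC cascade to one read.

    Only the 15-nt window adjacent to the anchor is pattern-checked (against
    the blueprint's terminal repeat unit at phase 0) — the rest of the barcode
    typically lies outside the read.
    """
    bp = bp or default_blueprint()
    loc = locate_anchor(read.seq, anchor, max_mismatch)
    if loc is None:
        return ExtractionHit(read.cell_tag, read.umi, "no_anchor")
    off, strand = loc
    sense = read.seq if strand == "+" else reverse_complement(read.seq)
    upstream = sense[:off]
    if empty_vector_signature and upstream.endswith(empty_vector_signature):
        return ExtractionHit(read.cell_tag, read.umi, "empty_vector")
    if len(upstream) < CLONE_ID_LENGTH:
        return ExtractionHit(read.cell_tag, read.umi, "short")
    cand = upstream[-CLONE_ID_LENGTH:]
    try:
        ok = segment_matches(cand, bp.suffix_segment.pattern, phase=0)
    except ValueError:
        ok = False
    if not ok:
        return ExtractionHit(read.cell_tag, read.umi, "pattern_fail")
    return ExtractionHit(read.cell_tag, read.umi, "ok", cand)


def dedup_and_resolve(
    hits: Iterable[ExtractionHit], min_umi_support: int = 1
) -> CellCloneTable:
    """Collapse hits to a cell→clone table with a QC report.

    Reads sharing a (cell, UMI) are consensus-collapsed to the majority clone
    identifier (ties discard the UMI).  UMIs are counted per (cell, clone);
    clones below ``min_umi_support`` within a cell are dropped; cells with two
    or more surviving clones are removed entirely and counted as multi-barcode.
    """
    status_counts: Counter[str] = Counter()
    per_umi: dict[tuple[str, str], Counter[str]] = defaultdict(Counter)
    cells_with_ok: set[str] = set()
    for h in hits:
        status_counts[h.status] += 1
        if h.status == "ok":
            per_umi[(h.cell_tag, h.umi)][h.clone_id] += 1
            cells_with_ok.add(h.cell_tag)

    umi_counts: dict[str, Counter[str]] = defaultdict(Counter)
    for (cell, _umi), clone_votes in per_umi.items():
        ranked = clone_votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # ambiguous consensus; discard the UMI
        umi_counts[cell][ranked[0][0]] += 1

    rows = []
    n_multi = 0
    for cell, clones in umi_counts.items():
        surviving = {c: n for c, n in clones.items() if n >= min_umi_support}
        if not surviving:
            continue
        if len(surviving) > 1:
            n_multi += 1
            continue
        (clone, support), = surviving.items()
        rows.append((cell, clone, support))

    assignments = pd.DataFrame(
        rows, columns=["cell_tag", "clone_id", "umi_support"]
    ).sort_values("cell_tag", ignore_index=True)
    n_candidates = len(cells_with_ok)
    qc = {
        "n_reads": int(sum(status_counts.values())),
        "status_counts": {s: int(status_counts.get(s, 0)) for s in STATUSES},
        "cells_with_ok_hit": n_candidates,
        "cells_multi_barcode": n_multi,
        "cells_assigned": len(assignments),
        "fraction_assigned": (len(assignments) / n_candidates) if n_candidates else 0.0,
    }
    return CellCloneTable(assignments, qc)


def extract_all(
    reads: Iterable[TaggedRead],
    bp: BarcodeBlueprint | None = None,
    anchor: str = DEFAULT_ANCHOR,
    empty_vector_signature: str = DEFAULT_EMPTY_VECTOR_SIGNATURE,
    max_mismatch: int = 0,
    min_umi_support: int = 1,
) -> CellCloneTable:
    """Run the full pipeline: per-read extraction then dedup/resolution."""
    hits = (
        extract_clone_id(r, bp, anchor, empty_vector_signature, max_mismatch)
        for r in reads
    )
    return dedup_and_resolve(hits, min_umi_support=min_umi_support)


# ---------------------------------------------------------------------------
# readers

def read_fastq_tagged(path: str) -> Iterator[TaggedRead]:
    """FASTQ with ``CB=`` and ``UB=`` key=value fields in the header line."""
    from Bio import SeqIO

    for rec in SeqIO.parse(path, "fastq"):
        fields = rec.description.split()
        tags = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
        yield TaggedRead(
            read_id=rec.id,
            seq=str(rec.seq),
            cell_tag=tags.get("CB", ""),
            umi=tags.get("UB", ""),
        )


def read_sam_tagged(path: str) -> Iterator[TaggedRead]:
    """SAM/BAM with CB and UB tags (as emitted by common scRNA-seq aligners)."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.query_sequence is None:
                continue
            cb = rec.get_tag("CB") if rec.has_tag("CB") else ""
            ub = rec.get_tag("UB") if rec.has_tag("UB") else ""
            yield TaggedRead(rec.query_name, rec.query_sequence, str(cb), str(ub))


def read_tagged(path: str) -> Iterator[TaggedRead]:
    """Dispatch on extension: .sam/.bam via pysam, otherwise FASTQ."""
    lower = path.lower()
    if lower.endswith((".sam", ".bam")):
        return read_sam_tagged(path)
    return read_fastq_tagged(path)
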