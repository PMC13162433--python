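"""Semi-random barcode grammar: IUPAC patterns, blueprints, libraries.

A clonal barcode is built from short degenerate repeat units tiled over fixed
segment lengths.  The default design concatenates a 60-nt ``WWSS`` segment, a
60-nt ``NSW`` segment, a fixed 25-nt gap (shared between the two synthesis
inserts, so counted once in the assembled barcode), a 60-nt ``WS`` segment and
a 60-nt ``SNW`` segment — 265 nt in total — flanked by fixed vector sequence.
The 33-nt right flank doubles as the anchor scanned for during extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml

# Degeneracy sets for the allowed IUPAC codes (W = A/T, S = G/C, N = any).
IUPAC_SETS: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "W": "AT",
    "S": "GC",
    "N": "ACGT",
}

#: 3' vector-backbone sequence scanned for in reads to locate the barcode.
DEFAULT_ANCHOR = "CAGATCTTAGCCACTTTTTAAAAGAAAAGGGGG"

#: Fixed literals not printed in the vector map; configurable placeholders.
DEFAULT_LEFT_FLANK = "GGTACCTCTAGAGCCACCGTGAACAGCT"
DEFAULT_GAP = "ACTAGCGTCAGTCATCGGATCCTAG"


class AlphabetError(ValueError):
    """A character outside the allowed DNA/IUPAC alphabet."""


def iupac_match(base: str, code: str) -> bool:
    """True iff ``base`` (A/C/G/T) lies in the degeneracy set of ``code``."""
    if base not in "ACGT" or len(base) != 1:
        raise AlphabetError(f"invalid DNA base: {base!r}")
    try:
        return base in IUPAC_SETS[code]
    except KeyError:
        raise AlphabetError(f"invalid IUPAC code: {code!r}") from None


def _validate_unit(unit: str) -> str:
    if not unit:
        raise AlphabetError("pattern unit must be non-empty")
    for ch in unit:
        if ch not in IUPAC_SETS:
            raise AlphabetError(f"invalid IUPAC code in pattern unit: {ch!r}")
    return unit


def segment_matches(seq: str, unit: str, phase: int = 0) -> bool:
    """Check ``seq`` against a tiled degenerate repeat unit.

    Position ``i`` of the sequence must match ``unit[(i + phase) % len(unit)]``.
    Patterns are anchored at the segment start (phase 0) by convention.
    """
    _validate_unit(unit)
    if not seq:
        raise ValueError("empty sequence")
    n = len(unit)
    return all(iupac_match(b, unit[(i + phase) % n]) for i, b in enumerate(seq))


@dataclass(frozen=True)
class Segment:
    """A degenerate repeat segment: ``pattern`` tiled over ``length_nt`` bases."""

    pattern: str
    length_nt: int

    def __post_init__(self) -> None:
        _validate_unit(self.pattern)
        if self.length_nt < 1:
            raise ValueError("segment length must be >= 1")


@dataclass(frozen=True)
class BarcodeBlueprint:
    """The assembled barcode grammar.

    ``segments`` are ordered; the fixed ``gap`` literal is inserted after
    ``gap_after`` segments (it appears in both synthesis inserts but only once
    in the assembled barcode, because the inserts overlap at the gap during
    assembly).  ``right_flank_anchor`` is the literal scanned for during
    extraction; the clone identifier is the barcode suffix adjacent to it.
    """

    left_flank: str = DEFAULT_LEFT_FLANK
    segments: tuple[Segment, ...] = (
        Segment("WWSS", 60),
        Segment("NSW", 60),
        Segment("WS", 60),
        Segment("SNW", 60),
    )
    gap: str = DEFAULT_GAP
    gap_after: int = 2
    right_flank_anchor: str = DEFAULT_ANCHOR

    def __post_init__(self) -> None:
        for s in (self.left_flank, self.gap, self.right_flank_anchor):
            for ch in s:
                if ch not in "ACGT":
                    raise AlphabetError(f"flank/gap must be literal DNA: {ch!r}")
        if not 0 <= self.gap_after <= len(self.segments):
            raise ValueError("gap_after out of range")

    def parts(self) -> list[Segment | str]:
        """Ordered assembled parts: segments with the gap literal interleaved."""
        out: list[Segment | str] = list(self.segments[: self.gap_after])
        if self.gap:
            out.append(self.gap)
        out.extend(self.segments[self.gap_after :])
        return out

    @property
    def suffix_segment(self) -> Segment:
        """The last degenerate segment — the source of clone identifiers."""
        return self.segments[-1]


def default_blueprint() -> BarcodeBlueprint:
    """The default 265-nt blueprint: WWSS×60, NSW×60, gap×25, WS×60, SNW×60."""
    return BarcodeBlueprint()


def blueprint_length(bp: BarcodeBlueprint) -> int:
    """Assembled barcode length in nt (gap counted once, flanks excluded)."""
    return sum(s.length_nt for s in bp.segments) + len(bp.gap)


def sample_barcode(bp: BarcodeBlueprint, rng: np.random.Generator) -> str:
    """Draw one barcode realizing the blueprint (reproducible under a seed)."""
    chunks: list[str] = []
    for part in bp.parts():
        if isinstance(part, str):
            chunks.append(part)
        else:
            unit = part.pattern
            chunks.append(
                "".join(
                    IUPAC_SETS[unit[i % len(unit)]][
                        rng.integers(len(IUPAC_SETS[unit[i % len(unit)]]))
                    ]
                    for i in range(part.length_nt)
                )
            )
    return "".join(chunks)


def sample_suffix(bp: BarcodeBlueprint, rng: np.random.Generator, length: int = 15) -> str:
    """Draw a clone identifier: the terminal ``length`` nt of the last segment.

    The suffix starts at an offset that preserves the repeat phase of the
    segment, so sampled identifiers validate against the segment pattern at
    phase 0 whenever the offset is a multiple of the unit length (true for the
    default 15-of-60 SNW design).
    """
    seg = bp.suffix_segment
    unit = seg.pattern
    offset = seg.length_nt - length
    if offset < 0:
        raise ValueError("suffix longer than terminal segment")
    return "".join(
        IUPAC_SETS[unit[(offset + i) % len(unit)]][
            rng.integers(len(IUPAC_SETS[unit[(offset + i) % len(unit)]]))
        ]
        for i in range(length)
    )


def sample_library(
    bp: BarcodeBlueprint, n: int, seed: int
) -> list[str]:
    """Sample ``n`` distinct barcodes (rejection on duplicates), seeded."""
    rng = np.random.default_rng(seed)
    seen: dict[str, None] = {}
    while len(seen) < n:
        seen.setdefault(sample_barcode(bp, rng), None)
    return list(seen)


def validate_barcode(seq: str, bp: BarcodeBlueprint) -> bool:
    """True iff ``seq`` satisfies every blueprint part at its offset."""
    if len(seq) != blueprint_length(bp):
        return False
    pos = 0
    for part in bp.parts():
        if isinstance(part, str):
            if seq[pos : pos + len(part)] != part:
                return False
            pos += len(part)
        else:
            if not segment_matches(seq[pos : pos + part.length_nt], part.pattern):
                return False
            pos += part.length_nt
    return True


def pattern_space(seg: Segment) -> int:
    """Number of distinct sequences the segment can realize (exact integer)."""
    out = 1
    unit = seg.pattern
    for i in range(seg.length_nt):
        out *= len(IUPAC_SETS[unit[i % len(unit)]])
    return out


def library_diversity(bp: BarcodeBlueprint) -> int:
    """Pattern space of the whole assembled barcode (product over segments)."""
    return math.prod(pattern_space(s) for s in bp.segments)


def expected_multi_tag_rate(diversity: int, n_cells: int) -> float:
    """Expected number of colliding cell pairs when labeling ``n_cells``.

    Birthday-style estimate ``n(n-1)/(2D)`` for a library of ``diversity``
    equally likely barcodes; supports the claim that low-MOI transduction from
    a multi-million-barcode library labels each cell uniquely.
    """
    if diversity < 1:
        raise ValueError("diversity must be >= 1")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    return n_cells * (n_cells - 1) / (2 * diversity)


# ---------------------------------------------------------------------------
# serialization

def blueprint_to_yaml(bp: BarcodeBlueprint, path: str) -> None:
    doc = {
        "left_flank": bp.left_flank,
        "segments": [{"pattern": s.pattern, "length_nt": s.length_nt} for s in bp.segments],
        "gap": bp.gap,
        "gap_after": bp.gap_after,
        "right_flank_anchor": bp.right_flank_anchor,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def blueprint_from_yaml(path: str) -> BarcodeBlueprint:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return BarcodeBlueprint(
        left_flank=doc["left_flank"],
        segments=tuple(Segment(d["pattern"], int(d["length_nt"])) for d in doc["segments"]),
        gap=doc["gap"],
        gap_after=int(doc.get("gap_after", 2)),
        right_flank_anchor=doc["right_flank_anchor"],
    )


def write_fasta(sequences: Iterable[str], path: str, prefix: str = "bc") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{prefix}{i:06d}\n{seq}\n")
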