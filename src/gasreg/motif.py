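"""IUPAC degenerate motif scanning.

Specialized for the GAS element (TTCNNNGAA) but general over the full IUPAC
code.  An ``N`` in the *pattern* matches any of A/C/G/T; an ``N`` in the
*genome* matches nothing, so masked sequence can never produce a hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core_io import GenomicInterval, fetch_sequence
from .errors import BoundsError

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

GAS_MOTIF_STRING = "TTCNNNGAA"


@dataclass(frozen=True)
class MotifPattern:
    """An ordered IUPAC consensus with a human-readable label."""

    symbols: str
    label: str = ""

    def __post_init__(self):
        if len(self.symbols) < 1:
            raise ValueError("pattern must have length >= 1")
        sym = self.symbols.upper()
        for ch in sym:
            if ch not in IUPAC_SETS:
                raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern")
        object.__setattr__(self, "symbols", sym)

    def __len__(self) -> int:
        return len(self.symbols)

    def regex(self) -> "re.Pattern":
        # lookahead makes overlapping windows visible; group 1 carries the match
        body = "".join(
            s if len(IUPAC_SETS[s]) == 1 else f"[{IUPAC_SETS[s]}]" for s in self.symbols
        )
        return re.compile(f"(?=({body}))")


GAS_MOTIF = MotifPattern(GAS_MOTIF_STRING, label="GAS")


@dataclass(frozen=True)
class MotifHit:
    """A strand-resolved match; ``matched_sequence`` is always forward-strand."""

    interval: GenomicInterval
    strand: str
    matched_sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"hit strand must be + or -, got {self.strand!r}")
        if len(self.matched_sequence) != len(self.interval):
            raise ValueError("matched sequence length differs from interval length")


def reverse_complement(pattern: MotifPattern) -> MotifPattern:
    """Reverse and IUPAC-complement a pattern (GAS maps to itself)."""
    rc = "".join(IUPAC_COMPLEMENT[s] for s in reversed(pattern.symbols))
    return MotifPattern(rc, label=pattern.label)


def scan_sequence(
    sequence: str,
    pattern: MotifPattern,
    strands: str = "both",
    chrom: str = "seq",
    offset: int = 0,
) -> list:
    """Scan one sequence; offsets in the returned hits are relative to
    ``offset`` (default 0, i.e. sequence start).

    A window matches on '+' iff every base satisfies the pattern symbol, and
    on '-' iff the forward strand matches ``reverse_complement(pattern)``
    there.  Hits are sorted by start, '+' before '-'.  A pattern longer than
    the sequence yields an empty list.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    sequence = sequence.upper()
    hits = []
    for m in pattern.regex().finditer(sequence):
        start = m.start()
        hits.append(
            MotifHit(
                GenomicInterval(chrom, offset + start, offset + start + len(pattern)),
                "+",
                m.group(1),
            )
        )
    if strands == "both":
        rc = reverse_complement(pattern)
        for m in rc.regex().finditer(sequence):
            start = m.start()
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, offset + start, offset + start + len(pattern)),
                    "-",
                    m.group(1),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_intervals(
    genome: Mapping[str, str],
    regions: Sequence[GenomicInterval],
    pattern: MotifPattern,
    strands: str = "both",
) -> dict:
    """Scan a set of genomic regions; only windows fully contained in a region
    are reported, with genomic coordinates."""
    out: dict = {}
    for region in regions:
        seq = fetch_sequence(genome, region)  # raises BoundsError with region info
        out[region] = scan_sequence(
            seq, pattern, strands=strands, chrom=region.chrom, offset=region.start
        )
    return out


def unique_hit_windows(hits: Sequence[MotifHit]) -> set:
    """Distinct match windows regardless of strand (presence/absence view).

    Needed because a palindromic pattern like GAS reports the same window on
    both strands."""
    return {(h.interval.chrom, h.interval.start, h.interval.end) for h in hits}
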