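"""Core genomic types and readers/writers for FASTA, BED, bedGraph and gene tables.

Coordinate convention: 0-based half-open ([start, end)) everywhere, i.e. plain
BED semantics.  1-based inputs are never auto-detected.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .errors import BoundsError, FormatError

DIFFERENT_CHROM = math.inf
"""Sentinel returned by :func:`interval_gap` for cross-chromosome pairs."""

_VALID_STRANDS = ("+", "-", ".")
_SEQ_ALPHABET = re.compile(r"[^ACGTN]")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located span on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Peak:
    """A scored genomic feature (TF binding peak, histone mark, ...)."""

    interval: GenomicInterval
    name: str
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def with_score(self, score: float) -> "Peak":
        return replace(self, score=score)


@dataclass(frozen=True)
class CoverageStep:
    """One bedGraph step: constant coverage over an interval."""

    interval: GenomicInterval
    value: float


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware transcript model.

    ``cds_start``/``cds_end`` are the genomic bounds of the coding span and are
    ``None`` for non-coding genes.  The CDS endpoints must land inside exons.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise ValueError(f"{self.gene_id}: tx_end must exceed tx_start")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for ex in exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = ex.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: cds bounds must both be set or both empty")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError(f"{self.gene_id}: cds outside transcript span")
            if not any(ex.start <= self.cds_start < ex.end for ex in exons):
                raise ValueError(f"{self.gene_id}: cds_start not inside an exon")
            if not any(ex.start < self.cds_end <= ex.end for ex in exons):
                raise ValueError(f"{self.gene_id}: cds_end not inside an exon")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end of the transcript, strand-aware."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a multi-record FASTA into ``{chrom: uppercase sequence}``.

    Headers are parsed up to the first whitespace; record order is preserved.
    Sequences must be over {A, C, G, T, N} after case folding.
    """
    genome: dict = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"duplicate FASTA header {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = _SEQ_ALPHABET.search(seq)
        if bad:
            raise FormatError(
                f"invalid character {bad.group()!r} at offset {bad.start()} "
                f"in record {record.id!r}"
            )
        genome[record.id] = seq
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _fmt_score(score: float) -> str:
    # repr round-trips floats exactly; integers render without '.0' noise
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_bed(path, min_cols: int = 3) -> list:
    """Read a BED3/BED5/BED6 file into an ordered list of :class:`Peak`.

    Missing names are auto-generated as ``peak_<line>`` (1-based); missing
    scores default to 0 and missing strands to '.'.  Duplicate names are made
    unique by suffixing ``_2``, ``_3``, ...
    """
    if min_cols not in (3, 5, 6):
        raise ValueError(f"min_cols must be one of 3, 5, 6; got {min_cols}")
    peaks: list = []
    seen: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start ({start}) >= end ({end})")
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start ({start})")
            name = fields[3] if len(fields) > 3 and fields[3] else f"peak_{lineno}"
            if len(fields) > 4 and fields[4] != "":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            else:
                score = 0.0
            strand = fields[5] if len(fields) > 5 and fields[5] else "."
            if strand not in _VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            if name in seen:
                seen[name] += 1
                name = f"{name}_{seen[name]}"
            seen.setdefault(name, 1)
            peaks.append(Peak(GenomicInterval(chrom, start, end), name, score, strand))
    return peaks


def write_bed(peaks: Sequence[Peak], path, extra_columns: Optional[Mapping[str, Sequence]] = None) -> None:
    """Write peaks as BED6, optionally appending named extra columns after column 6.

    Round-trip contract: ``read_bed(write_bed(x)) == x`` field for field.
    """
    if extra_columns:
        for key, col in extra_columns.items():
            if len(col) != len(peaks):
                raise ValueError(f"extra column {key!r} has wrong length")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            row = [p.chrom, str(p.start), str(p.end), p.name, _fmt_score(p.score), p.strand]
            if extra_columns:
                row.extend(str(col[i]) for col in extra_columns.values())
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> list:
    """Read a 4-column bedGraph into a list of :class:`CoverageStep`."""
    steps: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            steps.append(CoverageStep(GenomicInterval(fields[0], start, end), value))
    return steps


def write_bedgraph(steps: Sequence[CoverageStep], path) -> None:
    with open(path, "w") as fh:
        for s in steps:
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t{_fmt_score(s.value) if s.value >= 0 else repr(s.value)}\n"
            )


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = (
    "gene_id",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "cds_start",
    "cds_end",
    "exon_sizes",
    "exon_starts",
)


def read_gene_table(path) -> list:
    """Read the tab-delimited gene table (BED12-like exon block encoding).

    ``exon_sizes``/``exon_starts`` are comma-separated; starts are relative to
    ``tx_start``.  Empty ``cds_start``/``cds_end`` mark non-coding genes.
    """
    genes: list = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENE_TABLE_COLUMNS:
            raise FormatError(
                f"{path}: bad gene-table header; expected {list(GENE_TABLE_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(GENE_TABLE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            rec = dict(zip(GENE_TABLE_COLUMNS, fields))
            gene_id = rec["gene_id"]
            try:
                tx_start, tx_end = int(rec["tx_start"]), int(rec["tx_end"])
                sizes = [int(x) for x in rec["exon_sizes"].rstrip(",").split(",")]
                starts = [int(x) for x in rec["exon_starts"].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field for {gene_id}") from exc
            if len(sizes) != len(starts):
                raise FormatError(f"{path}:{lineno}: exon_sizes/exon_starts mismatch for {gene_id}")
            exons = [
                GenomicInterval(rec["chrom"], tx_start + s, tx_start + s + w)
                for s, w in zip(starts, sizes)
            ]
            cds_start = int(rec["cds_start"]) if rec["cds_start"] != "" else None
            cds_end = int(rec["cds_end"]) if rec["cds_end"] != "" else None
            try:
                gene = GeneModel(
                    gene_id=gene_id,
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=tuple(exons),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            sizes = ",".join(str(len(ex)) for ex in g.exons)
            starts = ",".join(str(ex.start - g.tx_start) for ex in g.exons)
            cds_s = "" if g.cds_start is None else str(g.cds_start)
            cds_e = "" if g.cds_end is None else str(g.cds_end)
            fh.write(
                "\t".join(
                    [g.gene_id, g.chrom, g.strand, str(g.tx_start), str(g.tx_end), cds_s, cds_e, sizes, starts]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic and coverage scoring
# ---------------------------------------------------------------------------

def interval_gap(a: GenomicInterval, b: GenomicInterval):
    """Edge-to-edge gap in bp between two intervals.

    Returns 0 when the intervals overlap or abut, the separating distance
    otherwise, and :data:`DIFFERENT_CHROM` (infinity) across chromosomes.
    Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return DIFFERENT_CHROM
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def score_peaks_from_coverage(peaks: Sequence[Peak], coverage: Sequence[CoverageStep]) -> list:
    """Replace each peak's score with sum(step value x overlap width).

    Coverage steps must be sorted and non-overlapping per chromosome.
    """
    by_chrom: dict = {}
    for step in coverage:
        by_chrom.setdefault(step.interval.chrom, []).append(step)
    starts_by_chrom: dict = {}
    for chrom, steps in by_chrom.items():
        prev_end = -1
        for s in steps:
            if s.interval.start < prev_end:
                raise FormatError(
                    f"coverage steps overlap or are unsorted on {chrom} near {s.interval.start}"
                )
            prev_end = s.interval.end
        starts_by_chrom[chrom] = [s.interval.start for s in steps]

    out = []
    for peak in peaks:
        steps = by_chrom.get(peak.chrom, [])
        starts = starts_by_chrom.get(peak.chrom, [])
        total = 0.0
        i = bisect_left(starts, peak.start)
        if i > 0 and steps[i - 1].interval.end > peak.start:
            i -= 1
        while i < len(steps) and steps[i].interval.start < peak.end:
            ov = min(peak.end, steps[i].interval.end) - max(peak.start, steps[i].interval.start)
            if ov > 0:
                total += steps[i].value * ov
            i += 1
        out.append(peak.with_score(total))
    return out


def fetch_sequence(genome: Mapping[str, str], region: GenomicInterval) -> str:
    """Slice a region out of the genome, with bounds checking."""
    if region.chrom not in genome:
        raise BoundsError(f"chromosome {region.chrom!r} absent from genome")
    seq = genome[region.chrom]
    if region.end > len(seq):
        raise BoundsError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds chromosome "
            f"length {len(seq)}"
        )
    return seq[region.start : region.end]
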