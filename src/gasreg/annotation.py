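"""Peak-to-genome annotation.

Each peak is assigned exactly one category by its midpoint, with priority
promoter > three_prime_utr > exon > intron > distal > intergenic, and linked
to a target gene.  Category territories are strand-aware; the 3'UTR is the
exonic portion downstream of the CDS end.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core_io import GeneModel, GenomicInterval, Peak

CATEGORIES = ("promoter", "three_prime_utr", "exon", "intron", "distal", "intergenic")


@dataclass(frozen=True)
class AnnotationParams:
    promoter_upstream_bp: int = 1_000
    promoter_downstream_bp: int = 100
    distal_max_bp: int = 50_000
    link_max_bp: int = 100_000

    def __post_init__(self):
        for name in ("promoter_upstream_bp", "promoter_downstream_bp", "distal_max_bp", "link_max_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.distal_max_bp > self.link_max_bp:
            raise ValueError("distal_max_bp must not exceed link_max_bp")


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    category: str
    target_gene: Optional[str]
    tss_distance: Optional[int]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.target_gene is None) != (self.category == "intergenic"):
            raise ValueError("target_gene must be None exactly for intergenic peaks")


def promoter_window(gene: GeneModel, params: Optional[AnnotationParams] = None) -> GenomicInterval:
    """Strand-aware promoter interval around the TSS, clipped at position 0.

    '+' strand: [TSS - upstream, TSS + downstream); '-' strand mirrors it so
    the same bases relative to the TSS are covered on the other side.
    """
    if params is None:
        params = AnnotationParams()
    tss = gene.tss
    if gene.strand == "+":
        start = tss - params.promoter_upstream_bp
        end = tss + params.promoter_downstream_bp
    else:
        start = tss - params.promoter_downstream_bp + 1
        end = tss + params.promoter_upstream_bp + 1
    return GenomicInterval(gene.chrom, max(0, start), max(1, end))


def tss_distance(gene: GeneModel, position: int) -> int:
    """Signed strand-aware distance of a base from the TSS (negative = upstream)."""
    return position - gene.tss if gene.strand == "+" else gene.tss - position


def three_prime_utr_intervals(gene: GeneModel) -> List[GenomicInterval]:
    """Exonic bases downstream of the CDS end (empty for non-coding genes)."""
    if not gene.is_coding:
        return []
    if gene.strand == "+":
        lo, hi = gene.cds_end, gene.tx_end
    else:
        lo, hi = gene.tx_start, gene.cds_start
    out = []
    for ex in gene.exons:
        s, e = max(ex.start, lo), min(ex.end, hi)
        if s < e:
            out.append(GenomicInterval(gene.chrom, s, e))
    return out


def _in_any(pos: int, intervals: Sequence[GenomicInterval]) -> bool:
    return any(iv.start <= pos < iv.end for iv in intervals)


def _gene_category(gene: GeneModel, pos: int, params: AnnotationParams) -> Optional[str]:
    """This gene's best claim on a base, or None if it makes no claim."""
    pw = promoter_window(gene, params)
    if pw.start <= pos < pw.end:
        return "promoter"
    if gene.tx_start <= pos < gene.tx_end:
        if _in_any(pos, three_prime_utr_intervals(gene)):
            return "three_prime_utr"
        if _in_any(pos, gene.exons):
            return "exon"
        return "intron"
    d = tss_distance(gene, pos)
    if -params.distal_max_bp <= d < 0:
        return "distal"
    return None


def classify_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    params: Optional[AnnotationParams] = None,
) -> AnnotatedPeak:
    """Classify one peak by its midpoint and link it to a target gene.

    Among genes claiming the winning category, ties are broken by smaller
    absolute TSS distance, then lexicographic gene id.  Target linking is
    capped at ``link_max_bp`` from the TSS; a peak claimed by no gene is
    intergenic with no target.
    """
    if params is None:
        params = AnnotationParams()
    mid = peak.interval.midpoint()
    claims: Dict[str, List[Tuple[int, str, GeneModel]]] = defaultdict(list)
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        cat = _gene_category(g, mid, params)
        if cat is None:
            continue
        d = tss_distance(g, mid)
        # the owning-gene link is uncapped for structural categories; only
        # distal linking is bounded by link_max_bp (no-op at defaults since
        # distal_max_bp <= link_max_bp)
        if cat == "distal" and abs(d) > params.link_max_bp:
            continue
        claims[cat].append((abs(d), g.gene_id, g))
    for cat in CATEGORIES[:-1]:
        if claims[cat]:
            _, gid, g = min(claims[cat])
            return AnnotatedPeak(peak, cat, gid, tss_distance(g, mid))
    return AnnotatedPeak(peak, "intergenic", None, None)


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    params: Optional[AnnotationParams] = None,
) -> List[AnnotatedPeak]:
    if params is None:
        params = AnnotationParams()
    by_chrom: Dict[str, List[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    return [classify_peak(p, by_chrom.get(p.chrom, ()), params) for p in peaks]


def category_distribution(annotated: Sequence[AnnotatedPeak]) -> Dict[str, Tuple[int, int]]:
    """Per category: (peak count, distinct target-gene count).

    Both units are reported because published summaries mix them.
    """
    counts: Dict[str, int] = defaultdict(int)
    genes: Dict[str, set] = defaultdict(set)
    for a in annotated:
        counts[a.category] += 1
        if a.target_gene is not None:
            genes[a.category].add(a.target_gene)
    return {cat: (counts[cat], len(genes[cat])) for cat in counts}
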