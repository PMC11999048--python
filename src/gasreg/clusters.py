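"""Enhancer-cluster (super-enhancer style) identification.

Peaks are stitched into candidate regions, regions are ranked by aggregate
score, the rank-score curve is normalized to the unit square, and regions
whose score exceeds the score at the first rank where the curve's slope
crosses the threshold are flagged as clusters (the classic rank-curve
tangent method).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .core_io import GenomicInterval, Peak
from .errors import DegenerateInputError


@dataclass(frozen=True)
class ClusterParams:
    stitch_distance_bp: int = 12_500
    slope_threshold: float = 1.0
    min_regions: int = 3

    def __post_init__(self):
        if self.stitch_distance_bp < 0:
            raise ValueError("stitch_distance_bp must be >= 0")
        if self.slope_threshold <= 0:
            raise ValueError("slope_threshold must be > 0")


@dataclass
class StitchedRegion:
    """A merged peak group; rank/curve fields are filled by
    :func:`build_rank_curve` and the flag by :func:`call_clusters`."""

    interval: GenomicInterval
    members: List[str]
    aggregate_score: float
    rank: Optional[int] = None
    normalized_x: Optional[float] = None
    normalized_y: Optional[float] = None
    is_cluster: bool = False


def stitch_peaks(peaks: Sequence[Peak], stitch_distance_bp: int = 12_500) -> List[StitchedRegion]:
    """Merge peaks whose inter-peak gap is <= ``stitch_distance_bp``.

    Output regions are pairwise disjoint with gaps strictly greater than the
    stitch distance, sorted by (chrom, start); aggregate score is the sum of
    member scores.
    """
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    regions: List[StitchedRegion] = []
    cur: Optional[dict] = None
    for p in ordered:
        if (
            cur is not None
            and p.chrom == cur["chrom"]
            and max(0, p.start - cur["end"]) <= stitch_distance_bp
        ):
            cur["end"] = max(cur["end"], p.end)
            cur["members"].append(p.name)
            cur["score"] += p.score
        else:
            if cur is not None:
                regions.append(_finish(cur))
            cur = {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "members": [p.name],
                "score": p.score,
            }
    if cur is not None:
        regions.append(_finish(cur))
    return regions


def _finish(cur: dict) -> StitchedRegion:
    return StitchedRegion(
        interval=GenomicInterval(cur["chrom"], cur["start"], cur["end"]),
        members=cur["members"],
        aggregate_score=cur["score"],
    )


def build_rank_curve(regions: Sequence[StitchedRegion]) -> List[StitchedRegion]:
    """Fill rank, normalized_x and normalized_y; returns regions sorted by
    ascending aggregate score (ties broken by genomic position).

    normalized_x = rank / (N - 1) (0 for N = 1); normalized_y = score / max.
    """
    if not regions:
        return []
    ordered = sorted(
        regions,
        key=lambda r: (r.aggregate_score, r.interval.chrom, r.interval.start),
    )
    max_score = ordered[-1].aggregate_score
    if max_score <= 0:
        raise DegenerateInputError("all aggregate scores are 0; rank curve undefined")
    n = len(ordered)
    for i, r in enumerate(ordered):
        r.rank = i
        r.normalized_x = i / (n - 1) if n > 1 else 0.0
        r.normalized_y = r.aggregate_score / max_score
    return ordered


def curve_slopes(regions: Sequence[StitchedRegion]) -> List[float]:
    """Central-difference slopes of the normalized curve, one-sided at the ends."""
    n = len(regions)
    if n < 2:
        return [0.0] * n
    x = [r.normalized_x for r in regions]
    y = [r.normalized_y for r in regions]
    slopes = []
    for i in range(n):
        lo = max(0, i - 1)
        hi = min(n - 1, i + 1)
        dx = x[hi] - x[lo]
        slopes.append((y[hi] - y[lo]) / dx if dx > 0 else 0.0)
    return slopes


def call_clusters(
    regions: Sequence[StitchedRegion], params: Optional[ClusterParams] = None
) -> Tuple[List[StitchedRegion], Optional[float]]:
    """Flag regions above the slope-threshold tangent point.

    The cutoff rank c is the smallest rank whose slope exceeds the threshold;
    cutoff_score is the aggregate score at c and membership is strict
    (score > cutoff_score).  With no qualifying rank, or fewer than
    ``min_regions`` regions, no clusters are called and the cutoff is None.
    """
    if params is None:
        params = ClusterParams()
    regions = list(regions)
    for r in regions:
        r.is_cluster = False
    if len(regions) < params.min_regions or not regions:
        return regions, None
    slopes = curve_slopes(regions)
    cutoff_rank = next(
        (i for i, s in enumerate(slopes) if s > params.slope_threshold), None
    )
    if cutoff_rank is None:
        return regions, None
    cutoff_score = regions[cutoff_rank].aggregate_score
    for r in regions:
        r.is_cluster = r.aggregate_score > cutoff_score
    return regions, cutoff_score


def identify_enhancer_clusters(
    peaks: Sequence[Peak], params: Optional[ClusterParams] = None
) -> Tuple[List[StitchedRegion], Optional[float]]:
    """stitch -> rank -> call, in one step."""
    if params is None:
        params = ClusterParams()
    regions = stitch_peaks(peaks, params.stitch_distance_bp)
    if not regions:
        return [], None
    regions = build_rank_curve(regions)
    return call_clusters(regions, params)
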