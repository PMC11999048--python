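"""High-confidence TF-peak filter.

A TF peak is high-confidence when it lies within ``window_bp`` (edge-to-edge,
boundary inclusive) of an H3K27ac peak AND its own interval fully contains at
least one GAS-motif window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_io import Peak, interval_gap
from .errors import BoundsError
from .motif import GAS_MOTIF, MotifPattern, scan_sequence, unique_hit_windows

NO_FEATURE = math.inf
"""Sentinel gap when no same-chromosome feature exists."""


@dataclass(frozen=True)
class ConfidenceParams:
    window_bp: int = 500
    motif: MotifPattern = GAS_MOTIF
    require_motif: bool = True

    def __post_init__(self):
        if self.window_bp < 0:
            raise ValueError(f"window_bp must be >= 0, got {self.window_bp}")


@dataclass(frozen=True)
class ConfidentPeak:
    """Per-peak audit record: both diagnostics plus the verdict."""

    peak: Peak
    nearest_k27_gap: float
    motif_hit_count: int
    passed: bool


def nearest_feature_gap(peak: Peak, features: Sequence[Peak]):
    """Minimum edge-to-edge gap to any same-chromosome feature.

    Returns :data:`NO_FEATURE` (infinity) when no candidate exists.
    """
    best = NO_FEATURE
    for f in features:
        g = interval_gap(peak.interval, f.interval)
        if g < best:
            best = g
            if best == 0:
                break
    return best


class _FeatureIndex:
    """Vectorized same-chromosome gap queries over a fixed feature set."""

    def __init__(self, features: Sequence[Peak]):
        self._starts: dict = {}
        self._ends: dict = {}
        grouped: dict = {}
        for f in features:
            grouped.setdefault(f.chrom, []).append(f)
        for chrom, feats in grouped.items():
            self._starts[chrom] = np.array([f.start for f in feats], dtype=np.int64)
            self._ends[chrom] = np.array([f.end for f in feats], dtype=np.int64)

    def min_gap(self, peak: Peak):
        starts = self._starts.get(peak.chrom)
        if starts is None:
            return NO_FEATURE
        ends = self._ends[peak.chrom]
        gaps = np.maximum(
            0, np.maximum(starts, peak.start) - np.minimum(ends, peak.end)
        )
        return float(gaps.min())


def filter_high_confidence(
    tf_peaks: Sequence[Peak],
    k27_peaks: Sequence[Peak],
    genome: Mapping[str, str],
    params: Optional[ConfidenceParams] = None,
):
    """Apply the two-condition filter to every TF peak.

    Returns ``(audit, passing)`` where ``audit`` holds one
    :class:`ConfidentPeak` per input peak (input order) and ``passing`` is the
    surviving subset of the original peaks, order preserved.

    The motif is searched inside the peak interval itself (full containment),
    never in the +/- window halo; motif_hit_count counts unique windows, so a
    palindromic motif matched on both strands counts once.
    """
    if params is None:
        params = ConfidenceParams()
    for p in tf_peaks:
        if p.chrom not in genome:
            raise BoundsError(f"peak {p.name}: chromosome {p.chrom!r} absent from genome")
        if p.end > len(genome[p.chrom]):
            raise BoundsError(
                f"peak {p.name}: interval exceeds chromosome {p.chrom} length"
            )

    index = _FeatureIndex(k27_peaks)
    audit = []
    passing = []
    for p in tf_peaks:
        gap = index.min_gap(p)
        seq = genome[p.chrom][p.start : p.end]
        hits = scan_sequence(
            seq, params.motif, strands="both", chrom=p.chrom, offset=p.start
        )
        n_windows = len(unique_hit_windows(hits))
        passed = gap <= params.window_bp and (
            n_windows >= 1 or not params.require_motif
        )
        audit.append(ConfidentPeak(p, gap, n_windows, passed))
        if passed:
            passing.append(p)
    return audit, passing
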