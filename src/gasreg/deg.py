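"""Differential-expression thresholding and binding integration.

Consumes per-gene statistics (total raw count, log2 fold change, p-value)
from an upstream DE model; applies the low-count prefilter, Benjamini-
Hochberg adjustment (on the kept genes only), strict fold-change/padj
thresholds, multi-set Venn decomposition, and the bound-gene intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError

STATUSES = ("up", "down", "not_significant", "filtered")


@dataclass(frozen=True)
class DEGParams:
    min_total_count: int = 10
    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05

    def __post_init__(self):
        if self.min_total_count < 0:
            raise ValueError("min_total_count must be >= 0")
        if self.lfc_threshold <= 0 or self.padj_threshold <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass(frozen=True)
class DEGStat:
    gene_id: str
    total_count: int
    log2fc: float
    pvalue: float

    def __post_init__(self):
        if self.total_count < 0:
            raise ValueError(f"{self.gene_id}: total_count must be >= 0")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"{self.gene_id}: p-value {self.pvalue} outside [0, 1]")


@dataclass(frozen=True)
class DEGCall:
    stat: DEGStat
    padj: Optional[float]
    status: str

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def filter_low_counts(stats: Sequence[DEGStat], params: Optional[DEGParams] = None):
    """Split genes into (kept, filtered) by the inclusive total-count floor."""
    if params is None:
        params = DEGParams()
    kept = [s for s in stats if s.total_count >= params.min_total_count]
    filtered = [s for s in stats if s.total_count < params.min_total_count]
    return kept, filtered


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q.tolist()


def call_degs(stats: Sequence[DEGStat], params: Optional[DEGParams] = None) -> List[DEGCall]:
    """Prefilter, adjust, threshold.

    BH runs on the kept genes only (independent-filtering order); the
    fold-change and padj comparisons are strict.  Filtered genes carry no
    padj and status 'filtered'.  Output preserves input order.
    """
    if params is None:
        params = DEGParams()
    kept, _ = filter_low_counts(stats, params)
    kept_ids = {s.gene_id for s in kept}
    padj_map: Dict[str, float] = {}
    if kept:
        adj = bh_adjust([s.pvalue for s in kept])
        padj_map = {s.gene_id: q for s, q in zip(kept, adj)}
    calls = []
    for s in stats:
        if s.gene_id not in kept_ids:
            calls.append(DEGCall(s, None, "filtered"))
            continue
        q = padj_map[s.gene_id]
        if q < params.padj_threshold and s.log2fc > params.lfc_threshold:
            status = "up"
        elif q < params.padj_threshold and s.log2fc < -params.lfc_threshold:
            status = "down"
        else:
            status = "not_significant"
        calls.append(DEGCall(s, q, status))
    return calls


def genes_with_status(calls: Sequence[DEGCall], status: str) -> Set[str]:
    return {c.stat.gene_id for c in calls if c.status == status}


def venn_counts(named_sets: Mapping[str, Set[str]]) -> Dict[str, int]:
    """Exclusive-region counts for 2-5 named sets.

    Keys are '&'-joined set names (input order); all 2^k - 1 regions are
    present, zeros included.  Region counts sum to |union|.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 5:
        raise ValueError(f"venn_counts supports 2-5 sets, got {len(names)}")
    regions: Dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions["&".join(combo)] = 0
    universe = set().union(*named_sets.values())
    for element in universe:
        membership = tuple(n for n in names if element in named_sets[n])
        regions["&".join(membership)] += 1
    return regions


def bona_fide_targets(deg_genes: Set[str], bound_genes: Set[str]) -> Tuple[Set[str], float]:
    """DEGs directly bound by the TF, and the fraction of DEGs bound."""
    inter = set(deg_genes) & set(bound_genes)
    frac = len(inter) / len(deg_genes) if deg_genes else 0.0
    return inter, frac


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

DEG_STATS_COLUMNS = ("gene_id", "total_count", "log2fc", "pvalue")


def read_deg_stats(path) -> List[DEGStat]:
    """Read the per-gene statistics TSV (gene_id, total_count, log2fc, pvalue)."""
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != DEG_STATS_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {list(DEG_STATS_COLUMNS)}, got {list(df.columns)}"
        )
    stats = []
    for row in df.itertuples(index=False):
        try:
            stats.append(
                DEGStat(str(row.gene_id), int(row.total_count), float(row.log2fc), float(row.pvalue))
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return stats


def write_deg_calls(calls: Sequence[DEGCall], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [c.stat.gene_id for c in calls],
            "total_count": [c.stat.total_count for c in calls],
            "log2fc": [c.stat.log2fc for c in calls],
            "pvalue": [c.stat.pvalue for c in calls],
            "padj": [c.padj if c.padj is not None else "" for c in calls],
            "status": [c.status for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)
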