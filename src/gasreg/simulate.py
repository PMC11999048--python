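"""Deterministic synthetic fixture generator with planted ground truth.

Emits a complete desk-scale bundle (genome, gene models, TF and H3K27ac
peaks, coverage, per-gene DE statistics) plus a truth manifest, built so that
every planted label is recoverable by re-running the pipeline stages:

* peaks are grouped into loci separated by more than the default stitch
  distance (12.5 kb), so each locus becomes exactly one stitched region;
* true high-confidence peaks carry a planted GAS window and an overlapping-
  to-nearby H3K27ac partner; decoys violate exactly one condition (half lack
  the motif, half sit in dedicated loci whose only H3K27ac peak is at the
  fail offset, far enough that no neighbour can rescue them);
* planted clusters are loci whose member scores are boosted by a fixed
  multiplier, so they dominate the rank-score curve;
* every peak locus lies inside a host gene, making the bound-gene set
  deterministic; a configured fraction of planted up-DEGs are host genes.

Background sequence is i.i.d. uniform over ACGT, so accidental GAS windows
occur at the analytic rate (~4^-6 per strand per position); they are censused
in the manifest rather than scrubbed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_io import (
    CoverageStep,
    GeneModel,
    GenomicInterval,
    Peak,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gene_table,
)
from .errors import CapacityError
from .motif import GAS_MOTIF, MotifPattern, scan_sequence

CHROM = "chr1"
PEAK_WIDTH = (150, 250)
INTRA_LOCUS_GAP = (30, 80)
K27_WIDTH = 200
STITCH_GUARD_BP = 12_600  # > default stitch distance, so loci never merge
EDGE_MARGIN = 1_500


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    genome_bp: int = 5_000_000
    n_genes: int = 400
    n_tf_peaks: int = 6_000
    frac_high_confidence: float = 0.73
    n_planted_clusters: int = 25
    cluster_member_range: Tuple[int, int] = (3, 8)
    cluster_score_boost: float = 20.0
    k27_offset_pass_bp: int = 200
    k27_offset_fail_bp: int = 2_000
    n_deg_up: int = 60
    frac_deg_bound: float = 0.33
    score_mu: float = 1.0
    score_sigma: float = 0.6

    def __post_init__(self):
        if not 0.0 <= self.frac_high_confidence <= 1.0:
            raise ValueError("frac_high_confidence must be in [0, 1]")
        if not 0.0 <= self.frac_deg_bound <= 1.0:
            raise ValueError("frac_deg_bound must be in [0, 1]")
        for name in ("genome_bp", "n_genes", "n_tf_peaks", "n_planted_clusters", "n_deg_up"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.cluster_member_range
        if not 1 <= lo <= hi:
            raise ValueError("cluster_member_range must satisfy 1 <= lo <= hi")
        if not self.k27_offset_pass_bp <= 500 < self.k27_offset_fail_bp:
            raise ValueError("need k27_offset_pass_bp <= 500 < k27_offset_fail_bp")


@dataclass
class _PeakPlan:
    name: str
    start: int
    end: int
    kind: str  # true | nomotif | far_k27 | cluster
    score: float
    motif_start: Optional[int]
    cluster_id: Optional[str]
    locus_idx: int


@dataclass
class Fixture:
    """Paths of the emitted bundle plus the parsed truth manifest."""

    out_dir: Path
    genome_fa: Path
    genes_tsv: Path
    tf_peaks_bed: Path
    k27_peaks_bed: Path
    coverage_bedgraph: Path
    deg_stats_tsv: Path
    truth_json: Path
    truth: dict


def _choose_locus_size(config: FixtureConfig, plain_total: int, n_far: int, cluster_total: int) -> int:
    """Smallest peaks-per-locus making the layout fit in the genome."""
    avg_pitch = (sum(PEAK_WIDTH) / 2) + (sum(INTRA_LOCUS_GAP) / 2)
    per_locus_overhead = STITCH_GUARD_BP + 400 + config.k27_offset_fail_bp + K27_WIDTH
    for m in range(6, 301):
        n_plain = -(-plain_total // m) if plain_total else 0
        n_fail = -(-n_far // m) if n_far else 0
        n_loci = n_plain + n_fail + config.n_planted_clusters
        est = (
            2 * EDGE_MARGIN
            + (plain_total + n_far + cluster_total) * avg_pitch
            + n_loci * per_locus_overhead
        )
        if est <= 0.97 * config.genome_bp:
            return m
    raise CapacityError(
        f"genome of {config.genome_bp} bp cannot hold {config.n_tf_peaks} peaks "
        f"with the required locus separation"
    )


def generate_fixture(config: FixtureConfig, out_dir) -> Fixture:
    """Write the full fixture bundle; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_true = round(config.frac_high_confidence * config.n_tf_peaks)
    n_decoy = config.n_tf_peaks - n_true
    n_nomotif = n_decoy // 2
    n_far = n_decoy - n_nomotif

    lo, hi = config.cluster_member_range
    cluster_sizes = rng.integers(lo, hi + 1, size=config.n_planted_clusters)
    cluster_total = int(cluster_sizes.sum())
    if cluster_total > n_true:
        raise CapacityError(
            f"{cluster_total} cluster members exceed the {n_true} true peaks available"
        )
    plain_true = n_true - cluster_total
    plain_total = plain_true + n_nomotif
    m = _choose_locus_size(config, plain_total, n_far, cluster_total)

    # --- locus plan ------------------------------------------------------
    def _balanced_split(total: int, parts: int) -> List[int]:
        base, extra = divmod(total, parts)
        return [base + (1 if i < extra else 0) for i in range(parts)]

    loci: List[dict] = []
    if plain_total:
        n_plain_loci = -(-plain_total // m)
        # balanced composition: per-locus true and decoy counts each vary by
        # at most one, so every plain locus keeps a solid majority of true
        # peaks and no undersized stray region appears on the rank curve
        true_sizes = _balanced_split(plain_true, n_plain_loci)
        dec_sizes = _balanced_split(n_nomotif, n_plain_loci)
        for n_tru, n_dec in zip(true_sizes, dec_sizes):
            kinds = ["nomotif"] * n_dec + ["true"] * n_tru
            rng.shuffle(kinds)
            loci.append({"type": "plain", "kinds": kinds})
    for ci, size in enumerate(cluster_sizes):
        loci.append({"type": "cluster", "kinds": ["cluster"] * int(size), "cluster_id": f"cluster_{ci:03d}"})
    left = n_far
    while left > 0:
        size = min(m, left)
        left -= size
        loci.append({"type": "fail", "kinds": ["far_k27"] * size})
    rng.shuffle(loci)

    # --- walk the genome -------------------------------------------------
    peak_plans: List[_PeakPlan] = []
    k27_intervals: List[Tuple[int, int]] = []
    locus_bounds: List[Tuple[int, int, dict]] = []
    cursor = EDGE_MARGIN
    limit = config.genome_bp - EDGE_MARGIN
    for locus_idx, locus in enumerate(loci):
        locus_start = cursor
        last_peak_end = cursor
        for j, kind in enumerate(locus["kinds"]):
            w = int(rng.integers(*PEAK_WIDTH))
            start, end = cursor, cursor + w
            score = float(rng.lognormal(config.score_mu, config.score_sigma))
            motif_start = None
            if kind in ("true", "cluster", "far_k27"):
                # far-K27 decoys keep the motif: they must violate only the
                # proximity condition
                motif_start = start + (w - len(GAS_MOTIF)) // 2
            plan = _PeakPlan(
                name=f"tf_{len(peak_plans):05d}",
                start=start,
                end=end,
                kind=kind,
                score=score,
                motif_start=motif_start,
                cluster_id=locus.get("cluster_id") if kind == "cluster" else None,
                locus_idx=locus_idx,
            )
            peak_plans.append(plan)
            if kind in ("true", "cluster", "nomotif"):
                d = int(rng.integers(0, config.k27_offset_pass_bp + 1))
                k27_intervals.append((end + d, end + d + K27_WIDTH))
            last_peak_end = end
            cursor = end + int(rng.integers(*INTRA_LOCUS_GAP))
        locus_end = max(last_peak_end, k27_intervals[-1][1] if k27_intervals else 0)
        if locus["type"] == "fail":
            k27_intervals.append(
                (last_peak_end + config.k27_offset_fail_bp,
                 last_peak_end + config.k27_offset_fail_bp + K27_WIDTH)
            )
            locus_end = k27_intervals[-1][1]
        locus_bounds.append((locus_start, last_peak_end, locus))
        cursor = locus_end + STITCH_GUARD_BP + int(rng.integers(0, 400))
        if cursor > limit:
            raise CapacityError(
                f"layout overran the genome at locus {locus_idx + 1}/{len(loci)} "
                f"(cursor {cursor} > {limit}); increase genome_bp or reduce peaks"
            )

    # --- sequence --------------------------------------------------------
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq_arr = bases[rng.integers(0, 4, size=config.genome_bp)].copy()
    planted_positions = []
    for plan in peak_plans:
        if plan.motif_start is not None:
            middle = bases[rng.integers(0, 4, size=3)]
            window = np.concatenate(
                [np.frombuffer(b"TTC", dtype="S1"), middle, np.frombuffer(b"GAA", dtype="S1")]
            )
            seq_arr[plan.motif_start : plan.motif_start + len(GAS_MOTIF)] = window
            planted_positions.append(plan.motif_start)
    genome = {CHROM: seq_arr.tobytes().decode("ascii")}

    # --- locus-level score shaping ---------------------------------------
    # The high-confidence member set of every locus is known exactly at
    # generation time (planted motifs plus accidental rescues of motif-less
    # decoys, which we detect by scanning the emitted sequence).  Member
    # scores are rescaled so each plain region's aggregate falls in a dense
    # bounded band and each planted cluster's aggregate is boosted by
    # cluster_score_boost above that band: the rank curve then has the flat
    # body / sharp-tail shape the tangent method expects, while per-peak
    # scores stay heavy-tailed (scaled log-normals).
    seq = genome[CHROM]
    rescued = set()
    for plan in peak_plans:
        if plan.kind == "nomotif":
            hits = scan_sequence(seq[plan.start : plan.end], GAS_MOTIF, strands="both")
            if hits:
                rescued.add(plan.name)
    hc_by_locus: Dict[int, List[_PeakPlan]] = {}
    plans_by_locus: Dict[int, List[_PeakPlan]] = {}
    for plan in peak_plans:
        plans_by_locus.setdefault(plan.locus_idx, []).append(plan)
        if plan.kind in ("true", "cluster") or plan.name in rescued:
            hc_by_locus.setdefault(plan.locus_idx, []).append(plan)
    mean_peak_score = float(np.exp(config.score_mu + config.score_sigma**2 / 2))
    for locus_idx, locus in enumerate(loci):
        if locus["type"] == "fail":
            continue
        members = hc_by_locus.get(locus_idx, [])
        if not members:
            continue
        if locus["type"] == "cluster":
            target = (
                len(members) * mean_peak_score * config.cluster_score_boost
                * float(rng.uniform(0.9, 1.2))
            )
        else:
            target = len(members) * mean_peak_score * float(rng.uniform(0.75, 1.35))
        factor = target / sum(p.score for p in members)
        for plan in plans_by_locus[locus_idx]:
            plan.score *= factor

    # --- genes -----------------------------------------------------------
    genes: List[GeneModel] = []
    gene_roles: Dict[str, str] = {}
    host_of_locus: Dict[int, str] = {}
    plain_host_counter = 0
    gene_records: List[Tuple[int, str, str, int]] = []  # (tx_start, role, strand, locus_idx)
    for locus_idx, (locus_start, last_peak_end, locus) in enumerate(locus_bounds):
        role = {"plain": "host_plain", "cluster": "host_cluster", "fail": "host_fail"}[locus["type"]]
        strand = "+" if rng.random() < 0.5 else "-"
        tx_start = locus_start - 500
        if locus["type"] == "plain":
            plain_host_counter += 1
            if plain_host_counter % 4 == 0:
                # align the TSS so the first peak's midpoint lands in the promoter
                first = next(p for p in peak_plans if p.locus_idx == locus_idx)
                tx_start = (first.start + first.end) // 2 - 50
                strand = "+"
        gene_records.append((tx_start, role, strand, locus_idx))
    # floaters in inter-locus gaps (never own a peak)
    n_floaters = config.n_genes - len(locus_bounds)
    if n_floaters < 0:
        raise CapacityError(
            f"n_genes={config.n_genes} is below the {len(locus_bounds)} host genes required"
        )
    gap_slots = []
    for i in range(len(locus_bounds) - 1):
        gap_start = locus_bounds[i][1]
        next_start = locus_bounds[i + 1][0]
        for off in (2_500, 5_200):
            mid = gap_start + config.k27_offset_fail_bp + K27_WIDTH + off
            if mid + 1_200 < next_start - 2_500:
                gap_slots.append(mid)
    if n_floaters > len(gap_slots):
        raise CapacityError(
            f"not enough inter-locus gaps for {n_floaters} floater genes "
            f"({len(gap_slots)} available)"
        )
    floater_slots = sorted(rng.choice(len(gap_slots), size=n_floaters, replace=False).tolist())
    for si in floater_slots:
        strand = "+" if rng.random() < 0.5 else "-"
        gene_records.append((gap_slots[si], "floater", strand, -1))

    gene_records.sort(key=lambda r: r[0])
    for gi, (tx_start, role, strand, locus_idx) in enumerate(gene_records):
        gene_id = f"g{gi:04d}"
        if role == "floater":
            tx_end = tx_start + 1_200
        else:
            tx_end = locus_bounds[locus_idx][1] + 500
            host_of_locus[locus_idx] = gene_id
        exon1 = GenomicInterval(CHROM, tx_start, tx_start + 150)
        exon2 = GenomicInterval(CHROM, tx_end - 350, tx_end)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=CHROM,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=tx_start + 30,
                cds_end=tx_end - 250,
                exons=(exon1, exon2),
            )
        )
        gene_roles[gene_id] = role

    bound_genes = sorted(
        {host_of_locus[i] for i, (_, _, loc) in enumerate(locus_bounds) if loc["type"] in ("plain", "cluster")}
    )
    unbound_genes = sorted(g for g, r in gene_roles.items() if r in ("host_fail", "floater"))

    # --- DE statistics ---------------------------------------------------
    n_bound_up = round(config.frac_deg_bound * config.n_deg_up)
    n_unbound_up = config.n_deg_up - n_bound_up
    if n_bound_up > len(bound_genes) or n_unbound_up > len(unbound_genes):
        raise CapacityError(
            "not enough bound/unbound genes to plant the requested DEG overlap"
        )
    bound_ups = sorted(rng.choice(bound_genes, size=n_bound_up, replace=False).tolist())
    unbound_ups = sorted(rng.choice(unbound_genes, size=n_unbound_up, replace=False).tolist())
    up_set = set(bound_ups) | set(unbound_ups)

    def _alt_pvalues(k: int) -> np.ndarray:
        # stratified Beta(0.1, 1) quantiles: marginal law preserved, but group
        # recovery under any p-threshold stays proportional to group size
        q = (np.arange(k) + 0.5) / k
        p = q ** 10.0  # Beta(0.1,1).ppf
        rng.shuffle(p)
        return p

    p_bound = _alt_pvalues(n_bound_up)
    p_unbound = _alt_pvalues(n_unbound_up)
    alt_p = dict(zip(bound_ups, p_bound)) | dict(zip(unbound_ups, p_unbound))

    deg_rows = []
    for g in genes:
        gid = g.gene_id
        if gid in up_set:
            total = int(rng.integers(200, 3001))
            lfc = float(rng.normal(2.0, 0.25))
            p = float(alt_p[gid])
        else:
            low = rng.random() < 0.05
            total = int(rng.integers(0, 10)) if low else int(rng.integers(20, 1501))
            lfc = float(rng.normal(0.0, 0.25))
            p = float(rng.uniform())
        deg_rows.append((gid, total, lfc, min(max(p, 0.0), 1.0)))

    # --- emit files ------------------------------------------------------
    genome_fa = out_dir / "genome.fa"
    genes_tsv = out_dir / "genes.tsv"
    tf_bed = out_dir / "tf_peaks.bed"
    k27_bed = out_dir / "k27_peaks.bed"
    cov_bg = out_dir / "coverage.bedGraph"
    deg_tsv = out_dir / "deg_stats.tsv"
    truth_path = out_dir / "truth.json"

    write_fasta(genome, genome_fa)
    write_gene_table(genes, genes_tsv)
    tf_peaks = [
        Peak(GenomicInterval(CHROM, p.start, p.end), p.name, p.score) for p in peak_plans
    ]
    write_bed(tf_peaks, tf_bed)
    k27_peaks = [
        Peak(GenomicInterval(CHROM, s, e), f"k27_{i:05d}", 0.0)
        for i, (s, e) in enumerate(sorted(k27_intervals))
    ]
    write_bed(k27_peaks, k27_bed)
    steps = [
        CoverageStep(GenomicInterval(CHROM, p.start, p.end), p.score / (p.end - p.start))
        for p in peak_plans
    ]
    write_bedgraph(steps, cov_bg)
    with open(deg_tsv, "w") as fh:
        fh.write("gene_id\ttotal_count\tlog2fc\tpvalue\n")
        for gid, total, lfc, p in deg_rows:
            fh.write(f"{gid}\t{total}\t{lfc!r}\t{p!r}\n")

    # --- truth manifest --------------------------------------------------
    census = background_motif_census(genome, GAS_MOTIF, planted=planted_positions)
    clusters_truth: Dict[str, dict] = {}
    for plan in peak_plans:
        if plan.cluster_id is not None:
            c = clusters_truth.setdefault(
                plan.cluster_id, {"chrom": CHROM, "start": plan.start, "end": plan.end, "members": []}
            )
            c["start"] = min(c["start"], plan.start)
            c["end"] = max(c["end"], plan.end)
            c["members"].append(plan.name)
    truth = {
        "config": asdict(config),
        "chrom": CHROM,
        "peaks": {
            plan.name: {
                "kind": plan.kind,
                "is_true_high_confidence": plan.kind in ("true", "cluster"),
                "planted_motif_positions": [plan.motif_start] if plan.motif_start is not None else [],
                "cluster_id": plan.cluster_id,
                "host_gene": host_of_locus.get(plan.locus_idx),
            }
            for plan in peak_plans
        },
        "clusters": clusters_truth,
        "genes": {
            g.gene_id: {
                "role": gene_roles[g.gene_id],
                "is_bound": g.gene_id in set(bound_genes),
                "is_true_deg": g.gene_id in up_set,
                "direction": "up" if g.gene_id in up_set else None,
            }
            for g in genes
        },
        "counts": {
            "n_true_high_confidence": sum(p.kind in ("true", "cluster") for p in peak_plans),
            "n_decoy_no_motif": sum(p.kind == "nomotif" for p in peak_plans),
            "n_decoy_far_k27": sum(p.kind == "far_k27" for p in peak_plans),
            "n_planted_clusters": len(clusters_truth),
            "n_bound_genes": len(bound_genes),
            "n_true_deg_up": len(up_set),
            "n_deg_up_bound": len(bound_ups),
        },
        "planted_motif_count": len(planted_positions),
        "background_motif_census": census,
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return Fixture(
        out_dir=out_dir,
        genome_fa=genome_fa,
        genes_tsv=genes_tsv,
        tf_peaks_bed=tf_bed,
        k27_peaks_bed=k27_bed,
        coverage_bedgraph=cov_bg,
        deg_stats_tsv=deg_tsv,
        truth_json=truth_path,
        truth=truth,
    )


def background_motif_census(genome: Dict[str, str], pattern: MotifPattern, planted=()) -> int:
    """Count forward-strand pattern windows whose start is not a planted site."""
    planted_set = set(planted)
    count = 0
    for chrom, seq in genome.items():
        for hit in scan_sequence(seq, pattern, strands="forward", chrom=chrom):
            if hit.interval.start not in planted_set:
                count += 1
    return count
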