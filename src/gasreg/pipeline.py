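"""End-to-end orchestration: simulate -> confident-peaks -> clusters ->
annotate -> deg -> integrate, with a strict-schema config and a JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .annotation import AnnotationParams, annotate_peaks, category_distribution
from .clusters import ClusterParams, identify_enhancer_clusters
from .confidence import ConfidenceParams, filter_high_confidence
from .core_io import (
    read_bed,
    read_bedgraph,
    read_fasta,
    read_gene_table,
    score_peaks_from_coverage,
    write_bed,
)
from .deg import (
    DEGParams,
    bona_fide_targets,
    call_degs,
    genes_with_status,
    read_deg_stats,
    venn_counts,
    write_deg_calls,
)
from .errors import ConfigError
from .motif import MotifPattern
from .simulate import FixtureConfig, generate_fixture

log = logging.getLogger("gasreg")


@dataclass
class PipelineInputs:
    genome_fa: Optional[str] = None
    tf_peaks_bed: Optional[str] = None
    k27_peaks_bed: Optional[str] = None
    genes_tsv: Optional[str] = None
    deg_stats_tsv: Optional[str] = None
    coverage_bedgraph: Optional[str] = None


@dataclass
class PipelineConfig:
    out_dir: str = "gasreg_out"
    seed: int = 0
    simulate: Optional[FixtureConfig] = None
    inputs: PipelineInputs = field(default_factory=PipelineInputs)
    confidence: ConfidenceParams = field(default_factory=ConfidenceParams)
    clusters: ClusterParams = field(default_factory=ClusterParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    deg: DEGParams = field(default_factory=DEGParams)
    deg_lists: Dict[str, str] = field(default_factory=dict)
    score_from_coverage: bool = False


_SECTION_TYPES = {
    "simulate": FixtureConfig,
    "inputs": PipelineInputs,
    "confidence": ConfidenceParams,
    "clusters": ClusterParams,
    "annotation": AnnotationParams,
    "deg": DEGParams,
}
_TOP_KEYS = {
    "out_dir",
    "seed",
    "simulate",
    "inputs",
    "confidence",
    "clusters",
    "annotation",
    "deg",
    "deg_lists",
    "score_from_coverage",
}


def _build_section(cls, data, keypath: str, errors: List[str]):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        errors.append(f"{keypath}: expected a mapping")
        return cls()
    allowed = {f.name for f in dc_fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in allowed:
            errors.append(f"{keypath}.{k}: unknown key")
            continue
        kwargs[k] = v
    if cls is ConfidenceParams and isinstance(kwargs.get("motif"), str):
        try:
            kwargs["motif"] = MotifPattern(kwargs["motif"])
        except ValueError as exc:
            errors.append(f"{keypath}.motif: {exc}")
            del kwargs["motif"]
    if cls is FixtureConfig and isinstance(kwargs.get("cluster_member_range"), list):
        kwargs["cluster_member_range"] = tuple(kwargs["cluster_member_range"])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{keypath}: {exc}")
        return None


def parse_config(data: dict) -> PipelineConfig:
    """Validate a raw config mapping (strict schema) into a PipelineConfig."""
    errors: List[str] = []
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])
    for key in data:
        if key not in _TOP_KEYS:
            errors.append(f"{key}: unknown key")
    cfg = PipelineConfig()
    cfg.out_dir = str(data.get("out_dir", cfg.out_dir))
    if "seed" in data:
        if not isinstance(data["seed"], int):
            errors.append("seed: must be an integer")
        else:
            cfg.seed = data["seed"]
    for name, cls in _SECTION_TYPES.items():
        if name == "simulate" and "simulate" not in data:
            continue
        section = _build_section(cls, data.get(name), name, errors)
        if section is not None:
            setattr(cfg, name, section)
    if cfg.simulate is not None and "seed" not in (data.get("simulate") or {}):
        # single-seed policy: the pipeline seed drives the fixture
        cfg.simulate = _build_section(
            FixtureConfig, {**(data.get("simulate") or {}), "seed": cfg.seed}, "simulate", errors
        )
    if "deg_lists" in data:
        if not isinstance(data["deg_lists"], dict):
            errors.append("deg_lists: expected a mapping of name -> path")
        else:
            cfg.deg_lists = {str(k): str(v) for k, v in data["deg_lists"].items()}
    if "score_from_coverage" in data:
        if not isinstance(data["score_from_coverage"], bool):
            errors.append("score_from_coverage: must be a boolean")
        else:
            cfg.score_from_coverage = data["score_from_coverage"]
    if cfg.simulate is None:
        required = ("genome_fa", "tf_peaks_bed", "k27_peaks_bed", "genes_tsv", "deg_stats_tsv")
        for name in required:
            if getattr(cfg.inputs, name) is None:
                errors.append(f"inputs.{name}: required when not simulating")
            elif not Path(getattr(cfg.inputs, name)).exists():
                errors.append(f"inputs.{name}: file not found: {getattr(cfg.inputs, name)}")
    for name, path in cfg.deg_lists.items():
        if not Path(path).exists():
            errors.append(f"deg_lists.{name}: file not found: {path}")
    if errors:
        raise ConfigError(errors)
    return cfg


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError([f"unparseable config: {exc}"]) from exc
    return parse_config(data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the run report dict.

    Stage outputs and ``report.json`` are written under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = config.inputs

    if config.simulate is not None:
        log.info("stage simulate: generating fixture (seed %d)", config.simulate.seed)
        fixture = generate_fixture(config.simulate, out_dir / "fixture")
        inputs = PipelineInputs(
            genome_fa=str(fixture.genome_fa),
            tf_peaks_bed=str(fixture.tf_peaks_bed),
            k27_peaks_bed=str(fixture.k27_peaks_bed),
            genes_tsv=str(fixture.genes_tsv),
            deg_stats_tsv=str(fixture.deg_stats_tsv),
            coverage_bedgraph=str(fixture.coverage_bedgraph),
        )

    log.info("stage load: reading inputs")
    genome = read_fasta(inputs.genome_fa)
    tf_peaks = read_bed(inputs.tf_peaks_bed, min_cols=3)
    k27_peaks = read_bed(inputs.k27_peaks_bed, min_cols=3)
    genes = read_gene_table(inputs.genes_tsv)
    deg_stats = read_deg_stats(inputs.deg_stats_tsv)

    if config.score_from_coverage:
        if inputs.coverage_bedgraph is None:
            raise ConfigError(["inputs.coverage_bedgraph: required with score_from_coverage"])
        log.info("stage score: replacing peak scores from coverage")
        tf_peaks = score_peaks_from_coverage(tf_peaks, read_bedgraph(inputs.coverage_bedgraph))

    log.info("stage confident-peaks: %d TF peaks vs %d K27 peaks", len(tf_peaks), len(k27_peaks))
    audit, passing = filter_high_confidence(tf_peaks, k27_peaks, genome, config.confidence)
    write_bed(passing, out_dir / "confident_peaks.bed")
    with open(out_dir / "confident_peaks_audit.tsv", "w") as fh:
        fh.write("name\tnearest_k27_gap\tmotif_hit_count\tpassed\n")
        for a in audit:
            gap = "inf" if a.nearest_k27_gap == float("inf") else str(int(a.nearest_k27_gap))
            fh.write(f"{a.peak.name}\t{gap}\t{a.motif_hit_count}\t{a.passed}\n")

    log.info("stage clusters: stitching %d high-confidence peaks", len(passing))
    regions, cutoff = identify_enhancer_clusters(passing, config.clusters)
    with open(out_dir / "stitched_regions.bed", "w") as fh:
        for r in sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start)):
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"region_{r.rank}\t{r.aggregate_score!r}\t.\t{int(r.is_cluster)}\n"
            )
    with open(out_dir / "rank_curve.tsv", "w") as fh:
        fh.write("rank\tnormalized_x\tnormalized_y\taggregate_score\tis_cluster\n")
        for r in regions:
            fh.write(
                f"{r.rank}\t{r.normalized_x!r}\t{r.normalized_y!r}\t{r.aggregate_score!r}\t{int(r.is_cluster)}\n"
            )

    log.info("stage annotate: %d peaks vs %d genes", len(passing), len(genes))
    annotated = annotate_peaks(passing, genes, config.annotation)
    with open(out_dir / "annotated_peaks.tsv", "w") as fh:
        fh.write("name\tcategory\ttarget_gene\ttss_distance\n")
        for a in annotated:
            fh.write(
                f"{a.peak.name}\t{a.category}\t{a.target_gene or ''}\t"
                f"{'' if a.tss_distance is None else a.tss_distance}\n"
            )
    distribution = category_distribution(annotated)

    log.info("stage deg: %d genes", len(deg_stats))
    calls = call_degs(deg_stats, config.deg)
    write_deg_calls(calls, out_dir / "deg_calls.tsv")
    up = genes_with_status(calls, "up")
    down = genes_with_status(calls, "down")

    log.info("stage integrate")
    bound = {a.target_gene for a in annotated if a.target_gene is not None}
    bona_fide, frac = bona_fide_targets(up, bound)
    with open(out_dir / "bona_fide_targets.tsv", "w") as fh:
        fh.write("gene_id\n")
        for g in sorted(bona_fide):
            fh.write(g + "\n")
    named_sets = {"up": up, "bound": bound}
    for name, path in config.deg_lists.items():
        with open(path) as fh:
            named_sets[name] = {line.strip() for line in fh if line.strip()}
    venn = venn_counts(dict(list(named_sets.items())[:5]))
    with open(out_dir / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=1, sort_keys=True)

    status_counts = {s: 0 for s in ("up", "down", "not_significant", "filtered")}
    for c in calls:
        status_counts[c.status] += 1
    report = {
        "version": __version__,
        "parameters": {
            "confidence": {
                "window_bp": config.confidence.window_bp,
                "motif": config.confidence.motif.symbols,
                "require_motif": config.confidence.require_motif,
            },
            "clusters": {
                "stitch_distance_bp": config.clusters.stitch_distance_bp,
                "slope_threshold": config.clusters.slope_threshold,
                "min_regions": config.clusters.min_regions,
            },
            "annotation": {
                "promoter_upstream_bp": config.annotation.promoter_upstream_bp,
                "promoter_downstream_bp": config.annotation.promoter_downstream_bp,
                "distal_max_bp": config.annotation.distal_max_bp,
                "link_max_bp": config.annotation.link_max_bp,
            },
            "deg": {
                "min_total_count": config.deg.min_total_count,
                "lfc_threshold": config.deg.lfc_threshold,
                "padj_threshold": config.deg.padj_threshold,
            },
            "seed": config.seed,
        },
        "input_checksums": {
            name: _sha256(getattr(inputs, name))
            for name in ("genome_fa", "tf_peaks_bed", "k27_peaks_bed", "genes_tsv", "deg_stats_tsv")
        },
        "counts": {
            "tf_peaks_in": len(tf_peaks),
            "k27_peaks_in": len(k27_peaks),
            "high_confidence_peaks": len(passing),
            "stitched_regions": len(regions),
            "enhancer_clusters": sum(r.is_cluster for r in regions),
            "cluster_cutoff_score": cutoff,
            "category_distribution": {
                cat: {"peaks": n_peaks, "genes": n_genes}
                for cat, (n_peaks, n_genes) in sorted(distribution.items())
            },
            "deg_status": status_counts,
            "bound_genes": len(bound),
            "bona_fide_targets": len(bona_fide),
            "bona_fide_fraction": frac,
            "venn": venn,
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info(
        "done: %d high-confidence peaks, %d clusters, %d bona fide targets",
        len(passing),
        report["counts"]["enhancer_clusters"],
        len(bona_fide),
    )
    return report
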