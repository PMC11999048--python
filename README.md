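# gasreg

GAS-motif-anchored regulatory genomics toolkit: a tested, reusable pipeline
for the downstream analysis of TF ChIP-seq and RNA-seq products —

1. **High-confidence TF peaks** — TF binding peaks that lie within ±500 bp
   (edge-to-edge, boundary inclusive) of an H3K27ac peak *and* fully contain
   at least one GAS element (IUPAC consensus `TTCNNNGAA`, which is its own
   reverse complement).
2. **Enhancer clusters (super-enhancer style)** — peaks are stitched
   (default gap ≤ 12.5 kb), stitched regions are ranked by aggregate score,
   the rank–score curve is normalized to the unit square, and regions above
   the score at the first rank whose curve slope exceeds 1 are flagged as
   clusters.
3. **Peak annotation** — midpoint-based assignment to exactly one of
   promoter / 3′UTR / exon / intron / distal / intergenic (priority in that
   order), with a target gene linked per peak.
4. **DEG integration** — ≥10-total-read prefilter, Benjamini–Hochberg
   adjustment on the kept genes, strict |log2FC| > 1 and padj < 0.05
   thresholds, multi-set Venn decomposition, and the intersection of DEGs
   with bound genes ("bona fide targets").
5. **Synthetic fixtures** — a deterministic generator that plants GAS
   motifs, decoy peaks violating exactly one filter condition, boosted
   enhancer clusters, and a configured DEG/bound-gene overlap, together with
   a machine-readable truth manifest for recovery testing.

All coordinates are 0-based half-open (BED convention).

## CLI

One executable with composable subcommands (logs to stderr, outputs to
files; exit codes: 0 ok, 2 config error, 3 data error):

```sh
gasreg simulate --seed 7 --out-dir fixture/
gasreg scan --fasta genome.fa --bed peaks.bed --motif TTCNNNGAA --out hits.bed
gasreg confident-peaks --tf-bed tf.bed --k27-bed k27.bed --fasta genome.fa \
    --window 500 --out-bed confident.bed --out-audit audit.tsv
gasreg clusters --peaks-bed confident.bed --stitch 12500 --slope 1.0 \
    --out-bed regions.bed --out-curve curve.tsv
gasreg annotate --peaks-bed confident.bed --genes-tsv genes.tsv \
    --out-tsv annotated.tsv --out-summary summary.json
gasreg deg --stats-tsv deg_stats.tsv --out-tsv deg_calls.tsv
gasreg integrate --deg-tsv deg_calls.tsv --annotated-peaks-tsv annotated.tsv \
    --out-targets targets.tsv --out-venn venn.json
gasreg run-all --config pipeline.yaml
```

`run-all` reads a strict-schema YAML config (unknown keys are errors), e.g.:

```yaml
out_dir: run1
seed: 7
simulate: {}          # or replace with an `inputs:` section of file paths
confidence: {window_bp: 500, motif: TTCNNNGAA}
clusters: {stitch_distance_bp: 12500, slope_threshold: 1.0}
deg: {min_total_count: 10, lfc_threshold: 1.0, padj_threshold: 0.05}
```

and writes every stage output plus `report.json` (counts at every stage,
parameter echo, input checksums).

## File formats

* FASTA (multi-record), BED3/5/6 (+extra columns on output), 4-column
  bedGraph.
* Gene table: TSV with header
  `gene_id chrom strand tx_start tx_end cds_start cds_end exon_sizes exon_starts`
  (BED12-like comma-separated exon blocks, starts relative to `tx_start`;
  empty cds fields mark non-coding genes).
* DE statistics: TSV with header `gene_id total_count log2fc pvalue`
  (upstream model fitting is consumed, not computed).
* Truth manifest (`truth.json`): per-peak labels (kind, planted motif
  positions, cluster id), per-gene labels (role, bound, planted DEG), the
  generator config echo, and a census of accidental background GAS windows.

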