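# ricecnv

Array-CGH copy-number analysis for small plant genomes: simulation of
two-channel tiling-array data, normalization, least-squares change-point
segmentation, stringent CNV calling, cross-sample CNVR consolidation,
and population-genetic / annotation / enrichment summaries.

## What it does

The pipeline mirrors a classic two-channel aCGH workflow:

1. **simulate** (`ricecnv.synthetic`) — probe layouts (~500 bp median
   spacing, 50–75-mer probes, shuffled array grid), planted loss/gain
   events (default log2 shifts −2.5 / +1.2), Gaussian ratio noise, a
   smooth spatial surface in grid coordinates, an intensity-dependent
   dye bias, and self–self null arrays.
2. **preprocess** (`ricecnv.preprocess`) — LOESS spatial correction on
   (x, y) feature position, then q-spline normalization between the two
   channels via a monotone cubic map through matched intensity
   quantiles.
3. **segment** (`ricecnv.segment`) — exact dynamic programming on
   `SSE + penalty × n_segments` per chromosome; the default penalty is a
   BIC-like rule `2·σ̂²·log n` with σ̂ from the median absolute
   successive difference.
4. **call** (`ricecnv.call`) — retain segments with mean log2 ≤ −2
   (loss) or ≥ +1 (gain); require 100 % of member probes to clear the
   directional cut-off; ≥ 5 probes and ≥ 1 kb per call.
5. **merge** (`ricecnv.cnvr`) — chain ≥ 1 bp-overlapping calls across
   samples into CNVRs, re-validate probes against a perfect-match table,
   drop CNVRs with < 5 probes or assembly-gap overlap, and emit a
   samples × CNVRs genotype matrix over {normal, loss, gain}.
6. **popgen** (`ricecnv.popgen`) — category frequencies, Nei gene
   diversity He = 1 − Σp², Fst = 1 − Hs/Ht, subspecies-specific and
   group-frequency screens, UPGMA clustering under uncentered
   correlation, one-way ANOVA on CNV lengths.
7. **annotate / enrich** (`ricecnv.annotate`, `ricecnv.enrich`) — gene
   (whole/partial) and segmental-duplication overlap, repeat/TE content
   of deleted regions (RepeatMasker `.out` or BED input), hypergeometric
   GO over-representation with Benjamini–Hochberg FDR.
8. **report** (`ricecnv.report`) — panel and coverage summary tables,
   half-up percentage bookkeeping, and the `run_pipeline` orchestrator
   (JSON manifest, byte-reproducible reruns).

## CLI

```bash
# full synthetic pipeline (20 samples, 12 chromosomes) into ./out
ricecnv run --seed 1 --out out

# or stage by stage
ricecnv simulate --seed 2 --samples S1,S2 --out sim
ricecnv preprocess sim/scan_S1.tsv --layout sim/layout.tsv \
    --genome sim/genome.tsv --sample S1 --out norm_S1.tsv
ricecnv segment norm_S1.tsv --layout sim/layout.tsv \
    --genome sim/genome.tsv --sample S1 --penalty auto --out seg_S1.tsv
ricecnv call norm_S1.tsv --layout sim/layout.tsv \
    --genome sim/genome.tsv --sample S1 --out calls_S1.tsv
ricecnv merge calls_*.tsv --layout sim/layout.tsv --genome sim/genome.tsv \
    --metadata metadata.tsv --out merged
ricecnv popgen merged/genotype.tsv --metadata metadata.tsv --out popgen
ricecnv enrich --study study.txt --background background.txt \
    --go-map go_map.tsv --out enrichment.tsv
```

`ricecnv run --config cfg.yaml` accepts a YAML file overriding any key
of `ricecnv.report.DEFAULT_CONFIG` (genome size, panel composition,
noise/artifact amplitudes, thresholds, penalties).

All on-disk formats are plain text: BED-like files are 0-based
half-open; everything else is TSV with a header. Coordinates in memory
are 1-based inclusive.

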