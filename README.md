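# nascentflow

Analysis pipeline for probing how transcription-machinery perturbations
remodel the RNA polymerase II interactome and nascent mRNA maturation, built
around five computational stages:

- **synthetic** — seeded generators for transcript annotations, metabolic-
  labeling (4sU/T>C) read counts, AP-MS intensity matrices with spiked
  interactors, and per-intron coverage profiles with optional premature-
  termination steps. Every generator is a pure function of (parameters, seed).
- **slam** — per-read T>C conversion counting (SAM/BAM with MD tags, SNP
  masking, minus-strand A>G handling), labeled-read classification,
  per-transcript aggregation, and RPMu normalization
  (`tcReadCount / Σ non-TC reads × 1e7`, per sample).
- **differential** — differentially-labeled-transcript calls between
  conditions at `p < 0.05` and `|log2FC| ≥ 1` (Welch default, Student's or a
  negative-binomial GLM optional, BH adjustment optional).
- **stratify** — gene-length trichotomization (short `[0,250)`, medium
  `[250,10001)`, long `[10001,∞)` nt), exon-count stratification (cutoff 30),
  per-stratum and target-set shift tests, and the labeling-time linearity
  check.
- **interactome** — AP-MS contrasts: zero intensities floored to 1, every
  sample normalized to the bait's intensity, replicate means, fold change vs
  control, Student's t-test, gained/lost classification, dual-response
  filtering at ±2 log2FC, UpSet-style set intersections, and protein-complex
  relative-binding summaries.
- **ipa** — a transparent change-point scorer for intronic polyadenylation:
  score `(mean_up − mean_down)/mean_up`, maximal-score site with leftmost tie
  break, thresholds on upstream depth and score, per-condition event counts.

## CLI

```sh
nascentflow simulate transcriptome --n-genes 500 --seed 1 --out ann.tsv
nascentflow simulate slam --annotation ann.tsv --labeling-time 10 \
    --conversion-rate 1e-4 --n-reads 2000 --seed 1 --out counts.tsv
nascentflow simulate interactome --n-proteins 500 --spike P001=-2 \
    --seed 1 --out intensities.tsv --design-out design.tsv
nascentflow simulate ipa --annotation ann.tsv --usage-fraction 0.5 \
    --depth 100 --seed 1 --out coverage.tsv

nascentflow quantify --sam reads.sam --annotation ann.tsv \
    --conversion-threshold 1 [--snp-mask mask.bed] --out counts.tsv
nascentflow diff --counts counts.tsv --design design.tsv \
    --alpha 0.05 --lfc 1 --method welch [--bh] --out diff.tsv
nascentflow stratify --differential diff.tsv --annotation ann.tsv \
    --cutoffs 250,10001 --exon-cutoff 30 --mode vs_zero --out strata.tsv
nascentflow interactome --intensities intensities.tsv --design design.tsv \
    --bait BAIT [--log] --out interactome.tsv
nascentflow ipa --coverage coverage.tsv --min-flank 100 --min-depth 10 \
    --min-score 0.25 --out events.tsv --counts-out ipa_counts.tsv

# end-to-end simulated run (deterministic per seed)
nascentflow run --simulate --seed 1 --outdir out/
```

Exit codes: 0 success, 2 configuration error, 3 input format error,
4 statistical degeneracy.

## Layout

```
src/nascentflow/
  synthetic.py     seeded generators + optional SAM emitter
  slam.py          conversion counting, aggregation, RPMu
  differential.py  DLT calls, volcano summary
  stratify.py      length/exon strata, shift tests, time-ratio
  interactome.py   floor → bait-normalize → test → set logic
  ipa.py           change-point scorer + event counting
  io.py            GTF/TSV/BED/SAM readers, TSV writers
  pipeline.py      config, manifest, end-to-end driver
  cli.py           click subcommands
  seeding.py       seed-splitting rule
  plots.py         optional figure writers
tests/             unit, property (hypothesis), and acceptance suites
scripts/acceptance.py
```
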