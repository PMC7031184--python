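# circaging

A tested pipeline for circular-RNA aging analysis on peripheral-blood
junction count data, with a fully synthetic data generator in place of raw
sequencing, cohort, cell-culture and mouse inputs. The stages:

1. **synthetic** — generates every input with planted ground truth:
   pooled young/old × RNase-R/mock junction-count libraries (negative-
   binomial counts, planted age-class memberships and fold changes), a
   population cohort with planted expression–phenotype effects, early/
   late-passage qPCR plates for four primary cell types, and a six-strain
   mouse panel with planted lifespan slopes.
2. **quantify** — back-spliced reads per million mapped reads (bpm) per
   circRNA per library, per-exon RPKM, presence calling on the treated
   libraries, and the 1–10 bar scaling of junction read depth.
3. **classify** — partitions circRNAs into young-only / old-only / shared
   classes, ranks shared circRNAs by |log2 fold change|, selects qPCR
   candidates (top-k per class), extracts host genes of the top-decile
   most abundant circRNAs, and runs a two-sided hypergeometric
   over-representation test with Holm (Bonferroni step-down) correction
   against user-supplied GMT gene sets.
4. **phenotype** — parental longevity score (PLS: z-scored parental death
   ages among participants 65+, premature deaths excluded at mother < 49 /
   father < 52 years, unweighted mean of available parental z-scores),
   grip-strength summaries, and the shared covariate encoding.
5. **associate** — global-mean qPCR normalization (median-collapsed
   technical replicates, ΔCt against the per-sample assay mean,
   2^−ΔCt, per-assay geometric-mean scaling), covariate-adjusted OLS
   expression–phenotype models with Bonferroni multiplicity control,
   early/late-passage one-way ANOVA with dysregulation counting, and
   mouse strain-lifespan regressions stratified by age group.

## CLI

One subcommand per stage plus an end-to-end run:

```sh
circaging run --outdir out/ --seed 1            # full synthetic pipeline
circaging simulate --outdir sim/ --seed 1       # generate inputs only
circaging quantify --counts sim/junction_counts.tsv --outdir q/
circaging classify --counts sim/junction_counts.tsv --outdir c/ \
    --k-per-class 5 --top-fraction 0.1 [--gene-sets sets.gmt]
circaging phenotype --cohort sim/cohort.tsv --outdir p/
circaging associate --cohort sim/cohort.tsv --expression sim/expression.tsv --outdir a/
```

All commands accept `--config config.yaml` (keys mirror the defaults in
`circaging/config.py`; unknown keys and out-of-range values are rejected
with an aggregated report). Every run writes TSV outputs plus a
`manifest.json` recording the semantic config hash, the seed and
per-file row counts; reruns with the same config are byte-identical.

## Layout

```
src/circaging/
  synthetic.py   input generators with planted ground truth
  quantify.py    bpm, RPKM, presence, depth bars
  classify.py    partitioning, ranking, candidate selection, enrichment
  phenotype.py   PLS, grip summaries, covariate encoding
  associate.py   qPCR normalization and all association models
  config.py      config parsing/validation
  pipeline.py    stage wiring and manifests
  cli.py         click entry point
  plotting.py    forest plots
  data/          bundled reference senescence-comparison table
tests/           pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
```
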