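# aneupipe

Analysis pipeline for long-term evolution experiments with disomic
(extra-chromosome) yeast strains, plus a synthetic-data generator that
emulates the experimental design with full ground truth.

Stages:

- **simdata** — simulates an annotated genome, per-line karyotype events and
  de novo mutations, windowed coverage, two-caller variant observations,
  expression counts and growth curves (negative-binomial noise, seeded,
  byte-reproducible).
- **karyocall** — coverage normalization against a euploid reference,
  binary-segmentation copy-number calling, karyotype-change classification
  (retained / whole loss / partial loss / segmental amplification).
- **mutcat** — two-caller consensus, ancestor subtraction, read-support and
  copy-number-aware allele-fraction filtering, coding-effect annotation
  (missense/nonsense/silent) and 750-bp promoter assignment.
- **mutstats** — apparent mutation rates u = m/(n·g) with SE = sqrt(u/(n·g)),
  composition-normalized substitution-type rates, 96-channel trinucleotide
  spectra and cosine signature similarity, exact two-sided binomial
  localization tests with BH adjustment, count–length correlation.
- **exprshift** — CPM filtering, RLE normalization, per-chromosome dosage
  medians, the expression shift-towards-reference statistic
  (1 − D_evolved/D_ancestor in log space over |FC| ≥ 1.5 genes), linear-model
  differential expression and shift association at FDR 0.1, hypergeometric
  gene-set enrichment.
- **growthfit** — doubling time as the reciprocal of the maximum slope of a
  GCV smoothing spline on log2(OD600).
- **bench_cli** — CLI orchestration plus the packaged per-strain mutation
  counts table and its worked-example summary (per-line means and rates).

## CLI

```sh
aneupipe all --outdir out --seed 17       # full simulated pipeline
aneupipe table1                           # worked-example summary
aneupipe karyotype --config cfg.yaml      # selected stages
```

Configuration is YAML (see `PipelineConfig`); every report embeds the
resolved config, its hash and the seed. Outputs are plain text: GFF3,
chromosome-size TSV, bedGraph coverage, minimal VCF call sets, TSV count
matrices and reports, JSON karyotype calls and truth records.

Exit codes: 2 config error, 3 missing input, 4 computation error.

## Notes

- Default simulation configs are scaled down (~1.2 Mb genome) so the demo
  pipeline runs in seconds; all sizes, rates and depths are configurable.
- The reference genome length used for worked-example rates defaults to
  1.212e7 bp and is surfaced in every report.
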