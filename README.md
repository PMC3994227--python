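# snpga

Genetic-algorithm search for high-risk multi-SNP genotype combination
models in case-control data, with exact 2x2 association statistics and an
exhaustive-search oracle.

A *model* of order *d* is a set of `(SNP, genotype)` pairs; an individual
matches it when carrying every listed genotype. A model's fitness is its
carrier frequency among cases minus its carrier frequency among controls
(models repeating a SNP score exactly 0). The package provides:

- `snpga.genotype_data` — CSV/TSV loading with allele-pair encoding
  (1 = major homozygote, 2 = het, 3 = minor homozygote), validation, and a
  seeded synthetic cohort generator (Hardy–Weinberg background plus an
  optionally embedded model).
- `snpga.model_space` — model notation (`SNP(1,4):2-2`), fitness, full
  enumeration and `exhaustive_best` (the oracle).
- `snpga.ga_engine` — the steady-state elitist GA: deterministic top-2
  selection, uniform crossover with a fair binary mask, per-position
  one-point mutation over the eligible element set, strictly-better
  replace-worst. Fully deterministic given a seed.
- `snpga.association_stats` — odds ratio `a·d/(b·c)`, Woolf 95% CI,
  two-sided Wald p-value, and the add-1-to-every-cell zero-cell correction;
  per-genotype single-SNP tests against the reference genotype; best-model
  report tables.
- `snpga.cli` — `search`, `simulate`, `stats`, `verify` subcommands.

## CLI

```sh
# simulate a cohort with an embedded 2-SNP risk model
snpga simulate --n-case 345 --n-control 290 --mafs 0.3,0.25,0.35,0.3,0.3 \
    --embed "SNP(1,4):2-2" --freq-case 0.42 --freq-control 0.35 \
    --seed 7 --out cohort.csv

# full pipeline: GA per order, statistics, report tables + results.json
snpga search cohort.csv --orders 2,3,4,5 --seed 1 --out-dir out/

# association tables only
snpga stats cohort.csv --model "SNP(1,4):2-2" --out-dir stats/

# GA-vs-exhaustive-oracle hit rates over seeds
snpga verify cohort.csv --orders 2,3 --seeds 100
```

Input format: CSV/TSV with a `status` column (`case`/`control`); other
columns are SNPs holding integer codes 1–3 or allele pairs (`GT`), with an
optional YAML sidecar declaring major/minor alleles per SNP.

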