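# colocus

Bayesian colocalisation of disease GWAS and *cis*-eQTL signals from summary
statistics.

A genomic region of `Q` SNPs is scored under five mutually exclusive
hypotheses — no causal variant (H0), a causal variant for the disease only
(H1), for expression only (H2), two distinct causal variants (H3), or one
shared causal variant (H4) — by combining per-SNP approximate Bayes factors
with per-SNP causal priors `p1`, `p2`, `p12`. The package covers the full
analysis around that computation:

- **`colocus.core`** — per-SNP log ABFs (from effect/SE or from
  p-value/MAF/N), region-level hypothesis priors, posterior probabilities
  PP0–PP4 (log-space throughout), and classification of pairwise analyses
  (overlap / suggestive / convincing, behind significance gates).
- **`colocus.eqtl`** — single-SNP OLS eQTL estimation, response-expression
  traits (stimulated − baseline), and inverse-variance fixed-effects
  meta-analysis with allele harmonisation.
- **`colocus.qc`** — SNP filters (MAF ≥ 0.005, call rate ≥ 0.99, |HWE z| ≤ 4,
  imputation info ≥ 0.3), ±200 kb *cis*-window probe selection, region
  eligibility (≥ 20 common SNPs), and the probe-overlap LD filter (r² > 0.6).
- **`colocus.calibration`** — empirical calibration of the shared-causal
  prior `p12` by matching the posterior expectation of colocalisation,
  averaged over pairwise analyses with PP3+PP4 > 0.8, to the prior
  expectation over a grid of candidate values.
- **`colocus.enrichment`** — candidate-gene enrichment (odds of PP4 > PP3 by
  candidate membership, odds ratio, Fisher exact test) and per-disease
  gene-level classification counts.
- **`colocus.synthetic`** — LD-structured haplotype panels (first-order
  Markov copy process), logistic case-control cohorts summarised by an
  allelic score test, and paired eQTL cohorts, for end-to-end testing
  without external data.
- **`colocus.data_io`** — VCF dosages (DS/GT), BED/TSV regions, probe
  annotations, GWAS summary tables and result tables, normalised to 1-based
  inclusive coordinates internally.
- **`colocus.pipeline`** — YAML-config-driven orchestration of
  QC → eQTL estimation → meta-analysis → colocalisation → classification →
  enrichment → calibration.

Default priors are `p1 = p2 = 1e-4` and `p12 = 1e-6`; all thresholds and
priors are configurable.

## Command line

```sh
# simulate a region with a shared causal variant and paired cohorts
colocus simulate --hypothesis H4 --q 500 --rho 0.95 --n-cases 2000 \
    --n-controls 2000 --n-eqtl 400 --seed 1 --out sim/

# per-SNP QC on a VCF
colocus qc --vcf sim/study1.vcf --report qc.tsv

# eQTL estimation (optionally meta-analysing two studies)
colocus eqtl --vcf sim/study1.vcf --expr sim/study1_expression.tsv \
    --probe P1 --out stats.tsv

# colocalise GWAS summary stats against the eQTL estimates
colocus coloc --gwas sim/gwas.tsv --eqtl stats.tsv \
    --n-cases 2000 --n-controls 2000 --p12 1e-6 --out result.tsv

# full pipeline from a YAML config (see colocus/pipeline.py for the schema)
colocus run --config run.yaml

# enrichment and p12 calibration from result tables
colocus enrich --pairs results/results.tsv --candidates genes.txt
colocus calibrate --pairs results_dir/ --grid 1e-7,1e-6,1e-5 --out calib.json

# validate any input file
colocus io validate sim/study1.vcf
```

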