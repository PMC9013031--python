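# panelconcord

Concordance analysis between a tumor-only (TO) and a matched tumor–normal
(TN) NGS gene-panel assay, bundled with a synthetic dual-assay cohort
simulator so the whole pipeline is exercisable without any external data.

The package models the common clinical-sequencing situation in which the
same tumor DNA is profiled by two commercial panels with different analytic
rules: the TO assay cannot subtract germline variants and caps its report at
14 variants ranked by actionability, while the TN assay subtracts germline
calls using matched-normal evidence and applies a tumor-cellularity-tiered
mean-depth requirement (200 / 250 / 500x). Discordant calls are assigned one
of five causes (germline leakage, reporting cap, caller filtering, low AF,
unexplained) and C>T/G>A substitution spectra quantify FFPE deamination
damage.

## Layout

| module | role |
|---|---|
| `panelconcord.variant_io` | TSV/VCF variant tables, validation, normalization, panel specs |
| `panelconcord.synthetic_data` | cohort simulator: germline/somatic/artifact truth + normal evidence |
| `panelconcord.assay_emulation` | TO and TN detection/reporting rules applied to a truth set |
| `panelconcord.concordance` | call matching, concordance rates, stratified summaries |
| `panelconcord.attribution` | five-way discordance cause attribution, substitution spectra |
| `panelconcord.stats_report` | exact 2xk test, rank tests, Spearman, report bundle |

Packaged fixtures (`panelconcord/data/`) define a TO-like panel (215 genes,
no matched normal, cap 14) and a TN-like panel (114 genes, matched normal,
tiered depth rule, uncapped); the two share 92 genes and comparative
analysis is restricted to that intersection. The panels' true AF floors and
read-support minimums are not publicly disclosed, so the fixture values
(TO 0.02, TN 0.05, 4 supporting reads) are package defaults, tunable per
config.

## CLI

```sh
panelconcord simulate --seed 1 --out-dir cohort/          # truth + metadata + normal evidence
panelconcord emulate  --cohort-dir cohort/ --seed 1 --out-dir reports/
panelconcord compare  --calls-a a.tsv --calls-b b.tsv --out-dir cmp/
panelconcord report   --seed 1 --out-dir run/             # full pipeline + report bundle
panelconcord worked-examples                               # canned-count rate arithmetic
```

`report` runs the whole chain (simulate → emulate both assays → match on the
shared genes → attribute discordance → summarize) deterministically for a
fixed seed; the default cohort is 30 samples in three specimen groups of 10
(fresh-frozen, high-quality FFPE, low-quality FFPE).

## Notes on the simulator

Germline heterozygotes have true AF exactly 0.5; somatic truth AF is
0.5 x cellularity x clonal fraction (diploid, no copy-number modeling);
FFPE artifacts are Poisson-injected per group (rates ordered
FF <= FFPE-H <= FFPE-L) with Beta(1, 40) AFs truncated below 10% and a
configurable C>T/G>A share. Observed calls are binomial draws at lognormal
per-variant depths. One seed drives counter-based per-sample substreams, so
cohorts are byte-reproducible and order-independent.
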