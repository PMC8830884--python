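# dnmkit

Pedigree-based detection of germline **de novo mutations (DNMs)** and
estimation of the **per-site per-generation mutation rate**, for anyone
running trio (or three-generation) short-read sequencing studies — in humans
or non-model species.

Direct estimates of the germline mutation rate come from counting Mendelian
violations in a father–mother–offspring trio: offspring alleles carried by
neither parent. Because sequencing, mapping and genotyping errors vastly
outnumber true mutations (tens per genome per generation), the field relies
on aggressive hard filtering, and every choice of filter changes both the
numerator (candidates) and the denominator (the part of the genome where a
mutation could have been seen). dnmkit implements that whole accounting
chain explicitly:

```
μ = N · (1 − FDR) / (2 · CG · (1 − FNR))
```

where `N` is the number of candidate DNMs surviving the filter stack, `FDR`
the false-discovery rate (from validation outcomes, manual curation, or the
deficit from the expected 50% transmission to a third generation), `CG` the
callable genome (sites where both parents are confidently homozygous for the
reference and every trio member passes the depth/quality filters), and `FNR`
the false-negative rate (spike-in recovery, the allelic-balance tail of true
heterozygotes, and/or the fraction of trusted variants removed by site-level
filters). Confidence intervals are Wilson score intervals on the corrected
count over the diploid callable denominator.

The package provides:

* **Filters** — every commonly used site filter (QUAL, QD, MQ, FS, SOR,
  rank-sum windows), depth filters (absolute, relative to individual or trio
  mean, σ-rule, exact Poisson test), genotype-quality filters (GQ per role or
  PL-gap per zygosity), parental alt-read caps, allelic-balance windows and
  exact binomial tests, strand, cluster, population/mask exclusion — all as
  composable predicates with full pass/fail provenance, plus five named
  presets (`LB`, `SB`, `CV`, `TT`, `RW`) transcribing published pipelines
  and `gatk_default` for the standard hard-filter set.
* **Pipeline** — Mendelian-violation detection (homozygous-reference
  configuration, all genotype configurations, or general allele-absence for
  multi-allelic sites) with per-stage candidate accounting.
* **Denominator** — count-based and probabilistic callable-genome
  estimation, three FNR estimators and independent-component combination.
* **Rates** — FDR estimators, the corrected rate with Wilson /
  Clopper–Pearson CIs, and binomial design calculators (allele dropout
  `0.5^depth`, somatic read-fraction leak-through).
* **Simulator** — a seeded synthetic trio generator (Poisson depths,
  binomial allele sampling with miscalls, standard diploid genotype
  likelihoods, injected DNMs, mosaic variants at chosen cell fractions,
  divergence and heterozygosity backgrounds) with a complete truth ledger,
  so every stage is testable without real data.
* **Reports** — call-set overlap counts, ti/tv, strand-collapsed mutation
  spectrum with CpG sub-classification, transmission summaries, one-at-a-time
  filter sweeps, and a standardised machine-readable run report.

## Worked example

Simulate a 200 kb trio at 40× with an (inflated, for demonstration) true
rate of 10⁻⁴ per site per haploid transmission plus five mosaic variants,
then call DNMs with the `LB` preset:

```bash
$ printf 'fam\tfather\t0\t0\t1\t0\nfam\tmother\t0\t0\t2\t0\nfam\tchild\tfather\tmother\t2\t0\n' > trio.ped
$ dnmkit simulate --genome-length 200000 --mu 1e-4 --n-somatic 5 \
    --seed 7 --out-vcf trio.vcf --out-truth truth.tsv
wrote 1941 records, 39 true DNMs
$ dnmkit call --vcf trio.vcf --ped trio.ped --child child --preset LB \
    --out-candidates candidates.tsv --out-accounting accounting.tsv
39 surviving candidates of 43 Mendelian violations
$ head -4 accounting.tsv
stage   in      out
input   1941    1941
mendelian_violation     1941    43
site_filter     43      43
```

Of 1941 variant records, 43 are Mendelian violations; the sample filters
remove four (somatic leak-through at low allelic balance, and low-quality
genotypes), leaving 39 candidates — here exactly matching the 39 injected
DNMs in `truth.tsv`. `candidates.tsv` carries, per candidate, the genotype
configuration and the observed-value/threshold provenance of every filter.

Rate assembly from counts (here: 33 validated and 6 failed of the resolved
candidates, a 2.75 Gb callable genome, a 5% FNR):

```bash
$ dnmkit rate --n-candidates 33 --validated 33 --failed 6 --cg 2.75e9 --fnr 0.05
{"mu": 5.34412955465587e-09, ..., "fdr": {"value": 0.15384615384615385,
 "method": "validation"}, "ci": [3.6957530525012853e-09, 7.727713478209756e-09],
 "ci_level": 0.95, "ci_method": "wilson"}
```

i.e. μ = 33·(1−0.154)/(2·2.75×10⁹·0.95) ≈ 5.3×10⁻⁹ per site per generation,
95% CI (3.7–7.7)×10⁻⁹. Study-design helpers:

```bash
$ dnmkit design --depth 15
{"allele_dropout_probability": 3.0517578125e-05,
 "expected_dropout_sites": 30.517578125, ...}
```

— at 15× coverage a heterozygote drops one allele entirely with probability
0.5¹⁵ ≈ 3.05×10⁻⁵, about 30 sites in a genome with a million heterozygous
positions; hence the usual advice to sequence parents well above 15×.

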