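# Methods

## The estimation problem

A germline de novo mutation (DNM) appears in an offspring's genotype and in
neither parent's. In a sequenced trio, candidate DNMs are Mendelian
violations; almost all raw violations are artifacts, so the estimate of the
per-site per-generation rate

μ = N·(1 − FDR) / (2·CG·(1 − FNR))

must make every correction explicit: N surviving candidates, the
false-discovery rate FDR among them, the callable genome CG (diploid, hence
the factor 2), and the false-negative rate FNR of the filter stack itself.
dnmkit implements the numerator (detection + filtering), the denominator
(CG + FNR), the corrections (FDR), and the uncertainty (binomial CI), plus a
simulator that generates data under the same read model the filters assume.

## Violation detection

Three admission modes, selectable per config:

* `homref_config` — both parents called 0/0, child 0/1. The standard
  restriction; it forfeits mutations on other backgrounds.
* `all_configs` — additionally 1/1 × 1/1 → 0/1 and 0/0 × 1/1 → 0/0 or 1/1.
* `allele_absence` — any child allele carried by neither parent, which also
  admits multi-allelic sites (e.g. a C/G father, G/G mother and A/G child).

The share of true DNMs lost by the homref restriction grows with
heterozygosity and with divergence to the reference genome; at 2% fixed
divergence about 1 in 50 DNMs arises where both parents are homozygous for
the alternative allele (`alt_background_fraction`). Genotypes are unphased
allele multisets throughout; indels and (outside allele-absence mode)
multi-allelic records are skipped and counted. Sex chromosomes are excluded
by default because allelic-balance and diploid-likelihood assumptions fail
on hemizygous calls; `include_chroms` overrides.

## The filter stack

All thresholds are strict inequalities exactly as conventionally printed
("GQ > 60" passes at 60, "QD < 2.0" fails below 2.0). A filter whose input
is absent is *not evaluable*: it neither passes nor fails the record but is
listed in the verdict, and a per-family `missing_policy` can turn
missingness into failure. Verdicts carry (filter, observed, threshold) for
every failure, so any removal can be replayed.

Stage order: violation detection → site annotations → depth →
genotype quality → parental alt reads → allelic balance → strand →
exclusion resources → clusters. Every per-candidate stage is a pure
predicate, so the surviving set is order-independent; the order only decides
which stage is credited in the accounting. Detection runs first so the
accounting counts candidates after each filter. The cluster rule (≥ k
candidates within a window, or pairs closer than a minimum distance) is
special: its verdict is computed on the **pre-filter violation set** and
applied last. Computing it on survivors would make removals depend on the
other filters' strictness, and tightening one filter could then resurrect a
previously clustered candidate — breaking the monotonicity property
(tightening any single threshold shrinks the candidate set) that the test
suite enforces over randomized configurations.

Depth bounds are a union of independently optional constraints — absolute
min/max, multiples of the individual or trio mean, a σ-window, and a
two-sided exact Poisson test at λ = mean depth — because published pipelines
mix them (one preset combines an absolute minimum of 10 with a maximum of
twice the individual mean). The Poisson filter removes calls with p below
the threshold; the opposite direction (reported in at least one published
description, almost certainly an erratum since it would remove nearly every
site) is available behind `poisson_reject_low=False`. Two-sided exact
p-values (Poisson depth, binomial allelic balance at p=1/2) are twice the
smaller tail, capped at 1; tests verify them against brute-force mass
summation for all n ≤ 30.

Allelic balance is alt reads over the sum of reads supporting the two
alleles being balanced (the reference by default; for a candidate on a
non-reference background, the child's other allele). AD order follows the
site's allele order; when AD is absent the AB filter reports not-evaluable
rather than inventing counts from DP.

Presets `LB`, `SB`, `CV`, `TT`, `RW` transcribe five published pipelines'
thresholds; `gatk_default` is the standard hard-filter set (QD < 2, MQ < 40,
FS > 60, SOR > 3, MQRankSum < −12.5, ReadPosRankSum < −8). TT's preset uses
allele-absence mode (it is the configuration that admits the multi-allelic
candidate that pipeline is known for) and mask-based site filtering,
including a homopolymer mask built from runs of ≥ 10 A or T. YAML configs
may start from a preset and override individual keys.

## Denominator

**Count-based CG** (default): over BP-resolution per-site input, count sites
where both parents are confidently called homozygous reference and all trio
members pass the configured depth and genotype-quality filters. This is
deliberately the same predicate family the candidates face, so numerator and
denominator are consistent; a DNM landing on a non-homref background is
neither counted nor callable, which keeps μ unbiased under the homref
restriction.

**Probabilistic CG**: from inherited heterozygous variants, estimate the
probability that a DNM would survive the depth/GQ/AB filters, binned by the
trio's minimum depth (bin width 5 by default; empty bins borrow the nearest
populated bin and are flagged), then sum that probability over the genome's
depth profile. This folds part of the FNR into CG, as some published
pipelines do.

**FNR** estimators:

* `spike_in` — convert background parental-homref sites into child
  heterozygotes (alt reads ~ Binomial(DP, ½) with miscalls, PL/GQ
  recomputed), run the full pipeline, report the missed fraction. Operates
  at the genotype-record level rather than on raw reads: the package's
  inputs are VCF-level and the simulator's likelihood model makes
  record-level injection faithful to what re-calling would produce.
* `ab_empirical` — fraction of forced heterozygotes (one parent 0/0, the
  other 1/1, so the child must be het) whose allelic balance falls outside
  the AB filter, with the same strict-inequality convention; a closed-form
  Binomial(depth, ½) version is provided for fixed depth.
* `site_filter_proportion` — fraction of a trusted variant set removed by
  the site-level annotation filters.

Independent components combine as FNR = 1 − Π(1 − FNRᵢ)
(`complement_product`; how published pipelines combined multiple sources is
generally unstated, and independence is the natural default given the
mechanisms are disjoint).

## FDR and the rate

FDR from validation is failed/(validated + failed), with unamplified
candidates in neither count; from transmission, max(0, 1 − 2·t/n) under the
model that true DNMs transmit at 50% and artifacts at 0%; manual-curation
and externally supplied (e.g. twin-discordance) values pass through. The
rate CI treats the corrected count N·(1−FDR) as a binomial numerator over
2·CG·(1−FNR) sites: Wilson score by default (well-behaved at the ~10⁻⁸
proportions involved; it is also the default of the commonly cited binomial
CI routine), Clopper–Pearson optionally. Uncertainty in FDR and FNR is not
propagated. The design calculators use the same binomial logic: allele
dropout 0.5^depth, and somatic leak-through P(X ≥ ⌈t·d⌉), X ~ Binomial(d, f)
with read fraction equal to cell fraction — the convention that reproduces
the standard worked values at 20× and 35×; halving for heterozygous somatic
variants is available as a flag but is not the default because it does not
reproduce them.

## Simulator

Per site: with probability equal to the divergence, a fixed difference
(both parents 1/1); otherwise, with probability 2·heterozygosity, a
polymorphic site at allele frequency ½ with parents drawn from
Hardy–Weinberg (so each parent is heterozygous at the configured per-site
rate, and forced-het and inherited-variant sites arise naturally); the child
inherits by Mendelian sampling. Germline DNMs are Binomial(2L, μ) in count,
uniform in position, with parent-of-origin recorded; the mutant base is
uniform over the three non-template bases, so mutations can be genotypically
invisible back-mutations or create multi-allelic sites — the truth ledger
records them all. Mosaic variants place alt reads at the cell fraction
(optionally halved). Depth is Poisson per individual; alt-supporting reads
are Binomial(DP, f) with f the genotype's allele fraction moved toward ½ ε
(symmetric per-read miscall, miscalls going to the other named allele);
PL/GQ/called genotypes follow the standard diploid likelihood (a read
matches a genotype allele with probability 1 − ε; heterozygote = even
mixture), normalized to min PL = 0, GQ capped at 99. Because the biallelic
model depends on reads only through (DP, alt count), results come from a
cached lookup table over all such pairs. Strand counts are Binomial(alt, ½);
low-quality-read alt counts use a Poisson side-channel at 5% of mean depth.

Only variant-looking sites are materialized as records (as in a real VCF);
all sites contribute to a BP-resolution depth/GQ table for CG estimation.
Everything is deterministic under (config, seed), to the byte in written
VCFs.

Defaults describe a macaque-like trio: heterozygosity 2.5×10⁻³ per site,
divergence to the (same-species) reference 5×10⁻³, 40× mean depth, miscall
rate 10⁻³, μ = 10⁻⁸ per site per haploid transmission.

**What the simulator does not model** — and what passing tests therefore do
not show about real data: read mapping and its artifacts (site annotations
QD/MQ/FS/SOR/rank-sums are drawn from stylized null distributions with a 1%
"artifact" fraction that violates common thresholds; their absolute scales
are meaningless), indels and structural variation, linkage, GC/ CpG
composition (mutant bases are uniform, so simulated spectra are flat),
mutation clustering (available only through an explicit cluster-injection
option), batch effects and contamination. Filter calibration against this
simulator validates the *machinery* (accounting, monotonicity, exact tests,
CI coverage), not field performance of any threshold choice.

A third generation can be appended: each true DNM transmits with probability
½ (configurable), the grandchild's other haplotype comes from a background
population model, and its calls use the same read model — enabling
transmission summaries and transmission-based FDR end to end.

## Numerical and degenerate-input conventions

Zero-depth calls have missing genotypes and uninformative PLs; records with
a missing child genotype are skipped and counted. Likelihoods use
contribution 0 for 0·log 0 so the error-free limit is exact; impossible
genotypes get a capped PL stand-in (9999). `fdr_from_transmission` clamps at
0. Estimators with empty bases (no spikes, no forced hets, no trusted
variants, CG = 0, FNR = 1) raise rather than return a default. Wilson bounds
are clamped to [0,1] and to contain the point estimate against floating-point
dust. The candidate TSV round-trips exactly through its reader.

## Scale of the shipped statistical checks

The test suite runs the monotonicity property over 50 random config pairs on
a 100 kb simulation, exact-test oracles for all n ≤ 30, AB-tail calibration
on 10⁴ heterozygotes, preset-wide null simulations on 50 kb, 500-site
spike-in completeness, and end-to-end rate recovery on 100 seeded replicates
of a 1 Mb genome at μ = 10⁻⁶ (genome and rate jointly scaled 100× from a
genome-scale study, preserving the expected count of ~2 DNMs per replicate),
requiring 95% Wilson CI coverage of the true rate in ≥ 90 of 100 replicates.
These sizes were chosen to give stable verdicts at interactive runtimes.
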