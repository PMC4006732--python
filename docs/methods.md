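# Methods

## The ASE test and its bias correction

At a heterozygous site with `ref` and `alt` filtered read counts
(`n = ref + alt`), the null hypothesis of equal allelic expression is not
`ref ~ Binomial(n, 0.5)`: reads carrying the non-reference allele align to
the reference genome slightly less efficiently, inflating the reference
fraction genome-wide. The test therefore uses the *empirical* null

    ref ~ Binomial(n, p̂),

with `p̂ = Σ ref / Σ (ref + alt)` pooled over all depth-passing sites in
scope. The default scope is per sample (tissue × assay), since mapping
ratios differ between libraries; a single global estimate is available via
`scope="global"`. Only the two depth filters gate which records enter the
estimate: including a significance filter would be circular, and
low-coverage records add noise without information. The estimate is clamped
to [1e-6, 1 − 1e-6].

The two-sided p-value uses the minimum-likelihood construction: the sum of
P(X = j) over every outcome j with P(j) ≤ P(observed), with a 1e-7 relative
tolerance for floating-point ties. Unlike doubling one tail, this is well
defined for any p̂ ≠ 0.5 and agrees exactly with brute-force enumeration
over all outcomes (property-tested for every outcome at n ≤ 50). The
implementation is vectorised: the boundary outcome on the far side of the
mode is found by bisection on the monotone tail of the pmf, so a full
dataset is tested with a few dozen vectorised pmf/cdf evaluations rather
than per-record loops. Inputs are canonicalised to p ≤ 0.5 so that the
allele-relabeling identity `test(a, b, p) = test(b, a, 1−p)` is bitwise
exact. An independent cross-check against `scipy.stats.binomtest` runs in
the test suite; the test itself never calls it.

Because the exact test is discrete it is slightly conservative: at depth
200 and α = 0.05 the simulated null rejection rate is ≈ 0.044 rather than
0.050.

## QC cascade

A measurement survives QC when, in order: bases below quality 10 were
removed at pileup time; each allele has ≥ 5 reads and the two alleles total
≥ 20; at most 5% of all reads support a third or fourth base ("bi-allelic
expression" — more is evidence of a paralog or systematic error); and the
site is intragenic. Significance is a *call*, not a QC criterion: `qc_pass`
ignores the p-value, `is_ase` requires `qc_pass` plus p below the
assay-specific α (0.05 RNA-seq, 0.01 targeted — the deep assay's power
justifies the stricter cutoff). An alternative depth rule (single total ≥
10, no per-allele minimum) is reachable through `FilterParams` for
compatibility with the lighter filtering sometimes applied to RNA-seq-only
analyses. The 5% bi-allelic threshold is a package choice; the underlying
filter concept has no standard quantification, and it is configurable.

## Cross-tissue classification

Per site, QC-passing per-tissue ratios are summarised by mean m and
dispersion σ (the *population* standard deviation: the tissue panel is the
entire object of study, not a sample, and n is small). Sites measured in
fewer than 3 tissues stay unclassified. The three-way rule:

| class        | condition |
|--------------|-----------|
| no ASE       | 0.35 ≤ m ≤ 0.65 and σ < 0.2 |
| shared ASE   | m < 0.35 or m > 0.65, σ < 0.2, ≥ 1 tissue p < 0.01 |
| variable ASE | σ > 0.2, ≥ 1 tissue p < 0.01 |

Everything else is unclassified, including σ exactly at the cutoff (the
strict inequalities satisfy neither rule). The balanced band is inclusive,
so m exactly 0.35 with low dispersion is "no ASE" regardless of
significance. The 0.2 cutoff is on the standard deviation, not the
variance: ratios bounded in [0,1] cannot have variance above 0.25, so a 0.2
variance cutoff would be nearly vacuous, and the replicate-reproducibility
sweep range 0.05–0.3 only makes sense on the SD scale. p-value significance
alone cannot separate the classes because with thousands of reads the
binomial test flags biologically trivial deviations — effect size does the
separating; the "≥ 1 significant tissue" requirement (configurable) guards
the ASE classes against pure-noise geometry. Whether the no-ASE class
should additionally require non-significance everywhere is left open by
design: classification is on ratio geometry, and significance counts are
carried on the profile for anyone who wants the stricter reading.

Monoallelic expression is called when a site has ≥ 5 testable tissues and
every ratio is ≥ 0.95 (alt expressed) or ≤ 0.05 (ref expressed); a site
whose ratios span both tails is never reported. The 0.95 threshold is a
package choice separating monoallelic from strong-but-partial ASE and is
configurable.

## Replicates

Technical replicates are merged by summing counts — testing the merged
record is then *identical* to testing the summed counts, which is the
motivation for merging rather than averaging. Concordance is quantified
per tissue as the Pearson r of QC-passing ratio pairs and the mean
|Δratio| per depth bin (binned by the smaller replicate depth; default
bins [20,100), [100,200), [200,500), [500,2000), [2000,∞)). The
classification sweep re-classifies each replicate's calls independently at
every grid point (ratio band × dispersion cutoff × tissue-exclusion
subset) and reports 3-class and binary (ASE vs not) label agreement; the
binary number can never be lower, since coarsening labels cannot break an
agreement. One subtlety: a dispersion cutoff far *below* the measurement
noise floor reclassifies essentially every site as variable in both
replicates and therefore agrees trivially; the informative degradation
happens for cutoffs inside the noise band (≈ 0.05 at depth 2000), which is
where the sweep grid starts.

## The generator

`simulate_dataset` draws, per site, an ASE class and a variant class, then
per-tissue true alternate fractions μ_t:

- no ASE: μ = 0.5 everywhere;
- shared ASE: μ_t = m ± N(0, 0.03) with m = 0.2 or 0.8 (direction a fair
  coin per site, fixed across tissues);
- variable ASE: μ_t ~ N(0.5, 0.3), clamped to [0.02, 0.98];
- monoallelic: μ = 0.99 or 0.01 everywhere;
- nonsense variants override the RNA μ with an NMD mean — 0.15 for rare
  (MAF < 5% or private), 0.30 for common — same direction in all tissues,
  while their DNA fraction stays 0.5. Their truth label is recorded as
  shared ASE, which is what the classifier should (and does) recover; the
  monoallelic truth likewise maps to an expected label of shared ASE, and
  `detect_monoallelic` identifies those sites separately.

Mapping bias is applied at read-sampling time as an odds multiplier β ≥ 1
on the reference allele: observed θ = μ / (β(1−μ) + μ), so a balanced site
shows reference fraction β/(β+1) — exactly the quantity the empirical-p̂
correction estimates, which is why bias recovery is testable in closed
form. Replicate noise is beta-binomial with intra-class correlation ρ
(default 0.005; configurable high-noise tissues get ρ = 0.05, emulating
degraded-RNA tissues such as post-mortem pancreas). Depths: the targeted
assay draws negative-binomial depth (mean 2000, shape 10) regardless of
expression; RNA-seq depth is Poisson around a log-normal per-gene
expression level (median ≈ 18 reads at the defaults, so a third of
measurements fall under the depth filters — the depth-decoupling argument
for targeted sequencing); exome DNA is Poisson mean 80 from two designated
DNA tissues. A small fraction (0.2%) of reads land on third/fourth bases.

Defaults (500 sites, 8 tissues, 2 replicates; classes 70/21/5/4%
no/shared/variable/monoallelic; variants 62/23/15% control/deleterious/
nonsense, mirroring a targeted panel's composition; β = 1.05) define the
conditions under which the recovery and concordance properties are
asserted. What the generator does **not** model: read-level artifacts
(duplicates, position-in-read effects), splice structure, primer
efficiency differences between targeted loci, genotyping error, and
site-to-site LD. Passing recovery tests therefore demonstrate that the
pipeline's inference is correct *under its own model assumptions*, not
that those assumptions hold for any particular sequencing protocol.

## Numerical and design choices

- Welch's t-test (unequal variances) for group comparisons; the pooled
  variant is available via `equal_var=True`. Groups with n < 2 are
  reported with missing statistics rather than dropped.
- Fisher exact p-values use the standard two-sided hypergeometric
  enumeration (via scipy, property-tested against explicit enumeration of
  all tables with the observed margins). The odds ratio is the sample
  ad/bc; a 0.5 Haldane–Anscombe correction is applied only when a zero
  cell makes it undefined, and flagged.
- "Deleterious" for enrichment means variant class ∈ {deleterious nsSNP,
  nonsense}; the flag is pluggable because site universes for such
  contrasts are study-specific.
- The DNA-bias filter removes a nonsense site only when its exome alt
  ratio is below 0.2 in *every* DNA sample with a usable call; a site with
  no DNA data is retained with a warning (absence of evidence).
- Coordinates are 1-based inclusive except BED (0-based half-open);
  conversion is confined to the readers. Multi-allelic VCF records are
  skipped with a warning — the data model is two observed alleles plus an
  aggregated `other_count`. Counts are strand-agnostic.
- Genotype concordance across all DNA samples in the VCF defines a
  high-confidence heterozygous site; discordant sites are dropped, not
  flagged.
- mpileup text is trusted as given: overlapping read pairs are however the
  upstream pileup engine resolved them.
- Problem sizes in the test suite and acceptance script (500-site default
  simulations, 200 generator replicates for the NMD contrast, 10,000-site
  calibration draws) were chosen so each property is measured well inside
  its sampling error while the whole suite runs in well under a minute of
  compute per module.

## Known limitations

- The binomial test ignores overdispersion; with thousands of reads,
  replicate-level noise (ρ > 0) makes trivially small deviations
  significant. This is inherent to the method and is exactly why
  classification weighs effect size, not p-values alone.
- A single p̂ per sample assumes mapping bias is homogeneous across sites;
  site-specific bias (e.g. at indels or in repetitive context) is not
  modeled.
- The classifier has no formal imprinting inference and no haplotype
  phasing; "monoallelic" is a ratio statement only.
- Cohort p-values are nominal; no multiple-testing correction across
  tissues is applied.
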