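# Methods

This note documents the statistical models behind `tumoronly`, the defaults
and their rationale, what the synthetic data generator does and does not
emulate, and the numerical choices that a user may want to revisit.

## Flag semantics and boundaries

Allele fractions are computed per alternative allele as high-quality
supporting bases over total high-quality bases at the position. Boundary
conventions are applied literally and uniformly: "below 20" and "below 10"
are strict (`<`), "5% or more" and "5 or more bases" are inclusive (`>=`),
and "more than 95%" is strict (`>`). The technical filter's allele-fraction
window [0.05, 0.95] is closed at both ends, consistent with the inclusive
5% used everywhere else.

Multi-allelic positions are evaluated jointly: the `CO` flag requires each
qualifying allele to be common in *some* population source, so a position
can be `CO` without any of `G5`/`DK`/`EG`/`EE` when two alleles are common
in different sources. Records are stored one row per allele, but flag
assignment always groups rows by (sample, chromosome, position).

Two readings of the `HF` rule are possible when it is triggered solely by a
shortage of non-alternative bases; we require at least one qualifying
allele in that case, and the allele itself to carry ≥ 5 supporting bases
when triggered by a fraction above 95%.

By default, `LQ`-flagged positions are excluded from the somatic funnel
(configurable via `FilterConfig.exclude_lq`); the technical depth/fraction
filter subsumes `LD`/`LF`.

## The germline allele-fraction test

A heterozygous germline variant is present in every cell, so its allele
fraction concentrates near 0.5 regardless of tumor content; a clonal
somatic variant is diluted to roughly purity/2. The manual filter
operationalizes "distributed evenly around 0.5" as: a position (or rs-id)
observed in ≥ 4 samples is germline when the median across-sample AAF lies
in [0.40, 0.60] **and** ≥ 70% of the observations lie in [0.30, 0.70]. The
windows are configurable; the defaults give ≥ 95% sensitivity on
Beta(20, 20) heterozygous draws of 8 observations while calling < 5% of
purity-0.3 somatic groups (fractions near 0.15) germline.

## Cluster detection and significance

Per gene, codons mutated in at least `seed_min_samples` (default 2)
distinct samples seed clusters; a seed absorbs neighbouring mutated codons
while successive gaps are at most `max_gap` (default 5) codons, and
overlapping extensions merge. A cluster's score is the fraction of the
gene's mutation events (sample-codon pairs) inside its interval, so a gene
with all mutations at one codon yields a single-position cluster with score
1.

Significance is assessed against a background in which the same number of
mutation events is placed at random codons — drawn from the gene's observed
silent-mutation positions when supplied (`background_source="synonymous"`,
the default, falling back to uniform per gene), otherwise uniformly over
the coding sequence. Two hundred background placements per gene are
clustered with the same procedure and their scores pooled.

Cluster scores are ratios of small integers and therefore heavily tied. A
plain empirical tail, and equally a normal approximation to the background
scores, is visibly non-uniform under the null; the default p-value is
therefore the Monte-Carlo tail rank with uniform randomized tie-breaking,

    p = (#{bg > s} + (1 + #{bg = s}) · U) / (B + 1),  U ~ Uniform(0, 1),

which is exactly uniform when the observed score is exchangeable with the
background draws. The randomization is driven by the same seeded generator
as the background, so results are reproducible. A normal-tail p
(`p_method="normal"`) and the background z-score are also reported for
users who prefer a deterministic, if conservative, summary.

## Survival analysis

Cluster-membership indicators (patients with ≥ 1 somatic variant in the
interval; clusters recurrent in > 5 patients) are the covariates. Patients
who died within a month of surgery or from post-operative complications,
and patients given neoadjuvant therapy, are excluded first. Eight groups
are analyzed: OS and PFS for the pooled cohort in stages I–IV and I–III,
and PFS for colon-only and rectal-only patients in both stage ranges.

**Stage 1 — penalized selection.** An elastic-net Cox model
(`scikit-survival`'s coordinate-descent path; mixing parameter `alpha`,
1 = pure LASSO) is fit over a 50-point regularization path. The penalty is
chosen by maximizing `2·loglik − df·log(n_events)` (a BIC on the path;
default). This rule is selection-consistent: in simulations with a planted
hazard ratio of 3 at 10% prevalence in 400 patients it selects the true
covariate in 20/20 seeds while selecting pure-noise covariates in ≤ 3% of
cases, whereas cross-validated partial likelihood — which optimizes
*prediction* — drags noise covariates in roughly two thirds of the time at
its optimum and loses the true covariate under a one-standard-error rule.
Because the goal here is identifying prognostic regions, not building a
risk score, BIC is the default; `selection="cv_min"`/`"cv_1se"` provide
10-fold cross-validated partial likelihood (Verweij–van Houwelingen
difference, fold-paired standard errors, fixed fold seed) for users who
want the predictive rule. The weakest-penalty end of the path, which
approaches the unstable unpenalized fit, is never chosen.

**Stage 2 — refit.** Penalized coefficients have no meaningful standard
errors, so each selected cluster is refit alone in an unpenalized Cox model
(`lifelines`), giving the hazard ratio and Wald p; the primary p-value is a
carrier vs non-carrier log-rank test. Kaplan–Meier curves can be exported
per cluster. Raw p-values are reported alongside a Benjamini–Hochberg
column; no correction is applied to the selection itself. Whether a joint
multivariable refit would be preferable is a modelling choice; the
per-interval refit is the literal two-stage procedure and keeps hazard
ratios interpretable per region.

## Panel scoring

Gene scores are row sums of a binary gene × feature membership matrix; the
ranking breaks ties by the highest colorectal mutation frequency (COSMIC
style) and then alphabetically, and is invariant to feature column order.
"Positive score" is read as score ≥ 1 (a threshold of ≥ 0 would admit
every gene; `min_score` is configurable). The frequency add-in is strict
(> 7%). The text-mining test is a one-sided (enrichment) Fisher exact test
on abstract co-mention counts with a strict genome-wide threshold
(5·10⁻⁷ by default); sidedness is a documented choice — depletion of
co-mentions is not evidence for panel inclusion. The network filter keeps
a candidate if it is one of the anchor genes (top-50 by length-normalized
mutation rate) or if ≥ 10% (inclusive) of its high-confidence interactors
are anchors. Gene identifiers are normalized through a deterministic
synonym table; a collision (two input names mapping to one symbol) is an
error rather than a silent merge.

## The synthetic cohort generator

The generator emulates a 200-patient colorectal cohort sequenced on a
~60-gene panel and is the test bed for every downstream stage:

* **Gene models**: 60 genes, 1 + Poisson(3) exons of 60–600 nt (multiples
  of 3), random strand, deterministic codon ↔ genomic mapping across exon
  boundaries.
* **Variant origins**: per sample, Poisson counts of common germline
  (mean 30), rare germline (3), somatic (12) and artifact (10) calls, drawn
  from shared allele catalogs so that recurrence across samples is
  realistic. Every emitted row carries exactly one origin label in the
  ground-truth table.
* **Allele fractions**: germline heterozygous Beta(20, 20) (symmetric about
  0.5 — the signature the manual filter keys on); somatic Beta with mean
  purity/2 and concentration 20 (a diploid heterozygous mutation under
  tumor-content dilution, purity Uniform(0.3, 0.9) since specimens under
  30% tumor nuclei would be excluded); artifacts Uniform(0.005, 0.045),
  emulating low-fraction FFPE damage. Observed support is binomial at
  Poisson(120) depth.
* **Population tables**: common alleles get AF ≥ 0.05 in all four sources
  (70%) or exactly one (30%), which creates common-without-single-source
  positions; ~5% of common alleles have a second alternative allele at the
  same position that is common in a *different* source, exercising the
  joint multi-allelic flag semantics. Rare alleles appear at AF < 0.05;
  somatic and hotspot alleles are absent everywhere.
* **Outcomes**: exponential baseline hazards (median OS 60 months, PFS 48),
  multiplied by each carried hotspot's hazard ratio, censored by an
  independent Uniform(0, 120 months); small probabilities of the two
  exclusion flags. Stage and cancer-type frequencies follow a stage I–IV
  surgical cohort (8/41/39/12% stages, 63% colon).
* **Planted hotspots** (defaults): G001 codons 10–12, prevalence 0.15,
  hazard ratio 2.5; G002 codon 25, prevalence 0.10, hazard ratio 3.0.
  Hotspot prevalences and effects are configurable, including width > 1
  for interval-shaped hotspots.

What the generator does **not** emulate: sequencing reads (depths and
qualities are drawn, not simulated from alignments), mapping and strand
artifacts, copy-number change and subclonal structure (somatic fractions
assume one diploid clone), microsatellite instability, linkage between
nearby germline variants, and population structure in the frequency
tables. Passing tests therefore demonstrate the correctness and
calibration of the *filtering and inference machinery* under its stated
assumptions, not performance on real FFPE capture data, where purity
estimation error, CNV-driven allele fractions and database incompleteness
will degrade the germline/somatic separation.

## Numerical and formatting choices

* Percentages are rounded half-up to one decimal (`percent_of_gene` uses
  exact integer decimals, never binary floats).
* The length-weighted gene frequency is `count / length_kb / n_samples`
  (scale 1, stated in the output header); the denominator for sample
  frequencies is always the explicitly passed number of analyzed samples.
* Recurrence counts are distinct-sample counts at every resolution (gene,
  exon, codon); a sample with two variants in one exon counts once there.
* The four default mask regions ship with the package; the TBP interval
  end coordinate is corrected for an obvious digit truncation (the printed
  end preceded its start), and the fifth character class of curation — the
  handful of rs-ids removed ad hoc during the original analyses — is
  supported as a user-supplied blocklist rather than hard-coded.
* Funnel stages conserve counts by construction and `validate()` asserts
  it; disabling every stage yields the identity.
* Determinism: the generator derives an independent seeded stream per
  stage from the single spec seed, so gene models, catalogs, frequency
  tables and cohorts are individually reproducible; cluster backgrounds
  and CV folds take explicit seeds.

## Problem sizes used in the validation suite

The test suite validates calibration and recovery at deliberately modest
sizes chosen to make the statistical checks sharp: 200-patient cohorts
(10 seeds) for germline-filter recovery, 1,000 null simulations of a
500-codon gene for cluster p-value uniformity, 20 seeds at n = 400 for
survival selection power and hazard-ratio recovery, and exhaustive
enumeration (all 2×2 tables with total ≤ 30; ~2,500-call boundary grids)
for the exact components.
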