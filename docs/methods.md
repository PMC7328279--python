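# Methods

This note documents the models, parameter choices and numerical conventions
behind `thiogvb`, and what the synthetic cohorts do and do not establish.

## Phenotype and cohort model

The clinical endpoint is the last-cycle 6-MP dose intensity percentage
(DIP): administered dose as a percentage of the protocol-planned dose over
the final 12-week maintenance cycle. DIP is nonnegative and unbounded above
(real cohorts include subjects titrated above 100% of the planned dose), so
the simulator truncates at 0 and imposes no upper cap. Intolerance analyses
condition on DIP ≤ cutoff, with 25% the primary clinical threshold and
15/25/35/45/60/80/100% the standard grid for ROC analyses.

A cohort is split into a discovery and a replication arm (default 244/76 of
320 subjects, i.e. the first 76.25% of subject ids are discovery). The
association screen runs on the **both-wild-type** subset: subjects who are
normal metabolizers for both *NUDT15* and *TPMT*, because those two genes'
known effects would otherwise dominate.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular patient data:

* **Genotypes.** Independent Hardy–Weinberg draws per variant at the
  configured allele frequency (no linkage disequilibrium, no population
  structure — deliberately out of scope). Missing calls are injected only
  when `missing_rate > 0` (default 0).
* **Star diplotypes.** Two alleles per gene drawn independently from
  configured frequencies. Default no-function frequencies — *NUDT15* 0.11
  (split 0.095 *3 / 0.015 *9) and *TPMT* 0.02 (*3C) — give an expected
  (0.89² · 0.98²) ≈ 76% both-gene NM fraction, i.e. the ~25% non-NM
  minority such cohorts show in East Asian populations. Variants tagged
  with `star_gene` take their genotype from the diplotype (count of
  no-function alleles), keeping VCF genotypes, diplotypes, metabolizer
  calls and burden scores mutually consistent.
* **DIP.** `baseline + age_effect·age + sex_effect·sex + Σ βᵥ·code(gᵥ) +
  N(0, σ)`, truncated at 0. Defaults: baseline 71.99, σ = 27.0 DIP units
  (the noncarrier stratum of such a cohort), age ~ N(7.0, 4.5²) years
  truncated at 0, sex ~ Bernoulli(0.571) with male = 1 everywhere,
  age/sex effects 0 (covariate adjustment is exercised regardless; the
  regression must not depend on their true values). The default variant
  panel carries one *CRIM1* recessive effect of −21.09 DIP units at allele
  frequency 0.255 (SIFT 0, CADD 25.3), dominant effects of −15 for the
  *NUDT15*/*TPMT* tag variants (matching the ~14-DIP-unit deficit of
  non-both-WT subjects), and nine null background variants spanning the
  SIFT/CADD filter boundaries.
* **Determinism.** One `numpy` Generator seeded from the config drives the
  whole cohort; a fixed config is bit-identical across runs.

What passing tests on these cohorts shows: the pipeline's arithmetic,
calibration (type-I error of the screen ≈ its nominal p cutoff), unbiased
effect recovery, and the qualitative two- vs three-gene ordering under a
true recessive third-gene effect. What they cannot show: performance under
LD, annotation error, star-allele calling error, dose-titration feedback or
real DIP distributions (which are left-skewed mixtures, not truncated
Gaussians).

## Association testing

* Adjusted regression: OLS of DIP on intercept + coded genotype + age +
  sex; two-sided t-test on the genotype coefficient; complete-case per
  variant (subjects with any missing field dropped, `n_used` reported).
  A genotype constant after the drop, or fewer than 5 complete cases, makes
  the model inapplicable — this reproduces the "NA" behaviour of recessive
  models for rare variants in small replication arms.
* Genetic codings: additive 0/1/2, dominant carrier = 1, recessive
  homozygote = 1.
* Fisher's exact test is two-sided by the sum-of-smaller-probabilities
  convention (the common one, matching `scipy.stats.fisher_exact`); a zero
  margin returns p = 1. The Cochran–Armitage trend test uses weights
  (0, 1, 2) and no continuity correction, with a standard-normal two-sided
  reference; it is hand-implemented (no installed library provides it) and
  cross-checked against an independent algebraic form and a value frozen
  from R's `prop.trend.test`.
* DIP strata for the categorical analyses are nested, not a partition:
  G0 (> 70%) is the tolerant control; G1 ≤ 70, G2 ≤ 60, G3 ≤ 45, G4 ≤ 35,
  G5 ≤ 25 and G6 < 15 (strict, by convention of the scheme).
* The discovery screen applies the additive-model regression gate
  (p < 0.01) and then the deleteriousness filter (SIFT ≤ 0.05 AND
  CADD ≥ 25, boundaries inclusive; a variant missing either score fails).
  No multiple-testing correction is applied at discovery — the
  deleteriousness filter plays that role by design, and the replication
  arm (p < 0.05, additive or recessive) provides the error control.

## Burden scoring

GVB of a gene = geometric mean of the SIFT scores of carried qualifying
variants; qualifying means genotype ≥ 1 (masked variants: = 2 only) and
SIFT strictly < 0.7; the empty set scores 1.0 so wild-type subjects sit at
the top of the scale. Choices that were genuinely open:

* **SIFT = 0 floor, default 0.001.** A literal geometric mean collapses to
  0 for every carrier of any SIFT-0 variant (the masked *CRIM1* variant
  itself has SIFT 0), destroying the ordering among multi-variant carriers
  and the meaning of burden cutoffs like ≤ 0.3 / ≤ 0.45. The floor keeps a
  single floored homozygote at cube-root(0.001) = 0.1 in a three-gene
  score, well below those cutoffs.
* **Zygosity.** A carried site contributes once whether heterozygous or
  homozygous (masked variants excepted). Double-counting homozygotes is a
  defensible alternative; it is not implemented because the score's
  definition counts variants, not alleles.
* **Missing SIFT.** Skipped (logged), never floored: a deleteriousness
  score cannot be invented.
* Multigene score = k-th root of the product of k gene scores;
  associative and order-free; a gene absent from the variant input scores
  1.0 for everyone (logged).

## Metabolizer phenotyping

Diplotype → phenotype: two normal alleles NM, one no-function IM, two
no-function PM, any uncertain allele indeterminate; assignment is symmetric
in allele order. The combined two-gene class is NM iff both genes are NM;
indeterminate calls route to the PM+IM risk arm (conservative toward
toxicity, logged). The shipped function table defaults *NUDT15*
*2/*3/*9 and *TPMT* *2/*3A/*3B/*3C to no function — reflecting the 2019
guideline update that moved *NUDT15*\*9 from 'uncertain' to 'no function' —
with a switch to restore the older 'uncertain' reading. Star-allele
*calling* from raw genotypes is out of scope; diplotypes are input.

## Evaluation

* Orientation: burden is "lower = worse"; condition positive is DIP ≤
  cutoff; test positive is score ≤ threshold (inclusive).
* AUC is the tie-corrected Mann–Whitney probability (via
  `sklearn.metrics`, oracle-tested against all-pairs counting). CIs are
  stratified bootstrap (positives and negatives resampled separately),
  2000 resamples by default, seeded; the interval is clamped to bracket
  the point estimate.
* Youden cutoffs scan every observed score as a candidate threshold; ties
  in J are broken toward the threshold classifying more subjects positive
  (higher sensitivity — a toxicity screen prefers over-flagging).
* Confusion metrics with a zero denominator are explicitly undefined
  (`None`), never 0. Report display rounds to 3 decimals, half-up; raw
  values are kept internally.
* The model-comparison report computes each GVB predictor's Youden cutoff
  per cohort (discovery, replication, combined separately), mirroring how
  such comparison tables are built; the categorical baseline has a single
  operating point, so its "AUC" is that of the 0/1 risk indicator.
* Single-gene contributions control for the other two genes by
  subsetting: *CRIM1* on both-WT subjects; *NUDT15* on WT-*TPMT*
  non-homozygote-*CRIM1* subjects; *TPMT* symmetrically. Degenerate
  subsets (one class empty, constant predictor) yield an explicit None.

## Problem sizes and numerical notes

Simulation-backed checks use 100–200 seeded replicates at the study's own
scale (n = 188–320): large enough that binomial/Monte-Carlo error bands
(±3 SE) are decisive for calibration and recovery claims, small enough to
keep the full suite under a minute of compute. The replication-power check
at n = 52 asserts power clearly above the null rate rather than a majority:
at ~3 expected homozygotes, the simulated power of the any-model p < 0.05
rule is ≈ 0.28 (null ≈ 0.10), and a single-cohort replication at that scale
is best understood as one draw from that distribution.

VCF annotation floats are single precision; SIFT/CADD are rounded to 4
decimals on read so that write→read round trips are exact for scores with
≤ 4 printed decimals. Genotypes are float arrays with `nan` as missing;
`./.` in VCF. All stochastic APIs take explicit seeds or Generators.

## Known limitations

No LD or population structure; no star-allele inference from sequence; no
dosage-weighted or CADD-based burden variants; no DeLong CIs or decision-
curve analysis; single-threaded. The discovery screen's behaviour under
correlated variants is untested by construction (independence is part of
the generator's design).
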