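# thiogvb

Gene-wise variant burden (GVB) scoring and multigene prediction of
thiopurine (6-mercaptopurine, 6-MP) intolerance in pediatric acute
lymphoblastic leukemia (ALL).

## The problem

6-MP dose tolerance during ALL maintenance therapy is strongly determined by
*NUDT15* and *TPMT* pharmacogenetic variants, yet many patients who are
normal metabolizers (NM) for both genes still suffer dose-limiting
hematological toxicity. The clinical endpoint used here is the **last-cycle
dose intensity percentage (DIP)** — the administered 6-MP dose as a
percentage of the protocol-planned dose over the final 12-week maintenance
cycle; low DIP means intolerance (DIP ≤ 25% is the conventional high-risk
cutoff in East Asian cohorts).

This package is for pharmacogenomics researchers who want to (a) screen
coding variants for association with tolerated dose in a
discovery/replication design, (b) aggregate a gene's variant load into a
single quantitative burden score, and (c) compare that score head-to-head
with categorical star-allele metabolizer phenotyping. Because cohorts of
this kind are rarely shareable, a first-class synthetic-cohort generator
reproduces the statistical structure of such a study (Hardy–Weinberg
genotypes, covariate effects, a recessive *CRIM1* missense effect, a ~25%
minority of non-NM subjects), so the whole pipeline is testable end to end.

## The score

For a gene *G* and one subject, with SIFT deleteriousness scores
*s₁ … s_k* of the coding variants the subject carries (restricted to
SIFT < 0.7; SIFT 0 floored at 0.001):

```
GVB^G = (s₁ · s₂ · … · s_k)^(1/k),          GVB^G = 1 if k = 0
```

Lower score = heavier predicted burden; a wild-type subject scores exactly
1. Multigene burden over a set {A, B, …} is the geometric mean of the gene
scores, e.g. `GVB^{A,B} = sqrt(GVB^A · GVB^B)`. Variants with a recessive
phenotype (default: *CRIM1* rs3821169, EAS allele frequency 0.255) are
**masked when heterozygous** — only homozygotes contribute.

Association screening is age- and sex-adjusted OLS of DIP on a coded
genotype (additive / dominant / recessive), with a discovery gate at
p < 0.01 plus in-silico deleteriousness (SIFT ≤ 0.05 and CADD ≥ 25) and a
replication gate at p < 0.05; categorical analyses across nested DIP strata
use Fisher's exact test and the Cochran–Armitage trend test. Classifiers
are compared by confusion-matrix metrics, ROC/AUC with stratified-bootstrap
CIs, and Youden-index optimal burden cutoffs at the seven standard DIP
cutoffs (15–100%).

## Worked example

```python
from thiogvb import (SimulationConfig, simulate_cohort, call_metabolizers,
                     select_both_wt, profile_cohort, roc_auc, youden_cutoff)

cohort = simulate_cohort(SimulationConfig(seed=1))          # 320 subjects
calls = call_metabolizers(cohort.diplotypes)                # NM/IM/PM per gene
both_wt = select_both_wt(cohort.subjects, calls)
print(f"{len(both_wt)} of {len(cohort.subjects)} subjects are both-wild-type")

profiles = profile_cohort(cohort.variants, cohort.subject_ids,
                          gene_sets=[("NUDT15", "TPMT"),
                                     ("NUDT15", "TPMT", "CRIM1")])
dip = cohort.subjects.set_index("subject_id").loc[profiles.index, "dip"]
intolerant = dip.to_numpy() <= 25.0
for label in ("NUDT15,TPMT", "NUDT15,TPMT,CRIM1"):
    scores = profiles[label].to_numpy()
    r = roc_auc(scores, intolerant, n_bootstrap=2000, seed=1)
    cut = youden_cutoff(scores, intolerant)
    print(f"GVB^{{{label}}}: AUC {r.auc:.3f} [{r.ci_low:.3f}, {r.ci_high:.3f}],"
          f" Youden cutoff {cut.threshold:.3g}")
```

prints

```
238 of 320 subjects are both-wild-type
GVB^{NUDT15,TPMT}: AUC 0.671 [0.534, 0.803], Youden cutoff 0.0316
GVB^{NUDT15,TPMT,CRIM1}: AUC 0.797 [0.686, 0.883], Youden cutoff 0.1
```

i.e. on this simulated cohort roughly three-quarters of subjects carry no
no-function *NUDT15*/*TPMT* allele, and adding the recessive *CRIM1* burden
to the classical two-gene score raises the AUC for predicting DIP ≤ 25%
(here 0.671 → 0.797; the bracketed interval is a stratified-bootstrap 95%
CI). The Youden cutoff is the burden threshold (score ≤ cutoff ⇒ predicted
intolerant) maximizing sensitivity + specificity − 1.

The same analysis is scriptable from the shell:

```sh
pgx simulate --seed 1 --out-prefix cohort
pgx gvb cohort.vcf --out gvb.tsv
pgx phenotype cohort.diplotypes.tsv --out metabolizers.tsv
pgx evaluate gvb.tsv metabolizers.tsv cohort.pheno.tsv --out report.tsv
# or everything at once, reproducibly:
pgx run --config run.yaml
```

Estimator-style interfaces (`GVBScorer`, `YoudenThresholdClassifier`)
compose with scikit-learn pipelines and model selection.

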