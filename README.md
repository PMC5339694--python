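# steatomics

A tested re-implementation of a multi-domain classifier pipeline for
hepatic steatosis (fatty liver, ≥5% fat on biopsy) in severe-obesity
cohorts.  The pipeline combines three data domains measured on the same
patients:

* **genomic** — a single steatosis-risk SNP (PNPLA3 rs738409-type), coded
  as the risk-allele count 0/1/2 with missing genotypes as a separate
  subgroup;
* **phenomic** — 19 pre-operative clinical variables, reduced by backwards
  stepwise logistic selection: a variable is dropped while its removal
  costs < 0.01 of the in-sample c-statistic;
* **proteomic** — a wide aptamer-style serum protein matrix (1129
  proteins), reduced by **stability selection**: B = 100 half-subsamples
  are drawn, an L1-penalized (lasso) logistic path is fitted on each over a
  shared λ grid, and each protein is scored by its maximum selection
  probability over the grid; the top 8 form a standardized logistic panel
  whose exp(coefficients) are odds ratios per 1 SD of log protein level.

Each domain yields a per-sample predicted probability of steatosis; a
second-level logistic regression stacks the scores ("late fusion"), and the
seven domain combinations are compared by the c-statistic / AUC

c = P(score_case > score_control) + ½·P(tie),

with percentile-bootstrap 95% CIs, repeated 80/20 split verification
(sensitivity/specificity at the training-split Youden threshold, 2500
replicates) and stratified 10-fold cross-validation.  Because the study's
patient-level data are not public, the package ships a seed-deterministic
synthetic cohort generator (577 samples split 443/134, Hardy–Weinberg
genotypes at risk-allele frequency 0.258 with 48 missing, a 30/21/26/23%
steatosis-grade marginal, planted phenomic signals and 8 planted protein
markers — 3 up, 5 down, 0.5 SD) on which every stage is exercised end to
end.  The published cohort-characteristics table is reproduced exactly from
its printed counts (uncorrected Pearson chi-square and 1-df Hardy–Weinberg
tests, plus a Freeman–Halton exact r×c Fisher test built by full
enumeration).

The audience is biostatisticians and methods developers who want a
reproducible, importable version of this classifier-construction recipe —
every operation (IRLS logistic MLE, coordinate-descent lasso path with KKT
guarantees, Mann–Whitney c-statistic, stability profiles, stepwise traces,
stacking, bootstrap/CV evaluation) is a documented library function.

## Worked example

Recompute the published cohort table's statistics from its printed counts:

```bash
$ python analysis/02_table1_statistics.py
            variable       method  statistic     df      p  published_p
       hwe_discovery     hwe_chi2     1.0583 1.0000 0.3036       0.3040
      hwe_validation     hwe_chi2     0.8965 1.0000 0.3437       0.3440
                 sex pearson_chi2     0.1903 1.0000 0.6626       0.6630
            diabetes pearson_chi2     0.0073 1.0000 0.9321       0.9320
        hypertension pearson_chi2     0.4100 1.0000 0.5220       0.5220
        dyslipidemia pearson_chi2     1.4382 1.0000 0.2304       0.2300
     steatosis_grade pearson_chi2     1.8135 3.0000 0.6120       0.6120
lobular_inflammation pearson_chi2     3.7013 2.0000 0.1571       0.1570
     pnpla3_genotype pearson_chi2     1.7978 2.0000 0.4070       0.4070
                race   fisher_rxc     0.2430    NaN 0.7346          NaN

9/9 chi-square-family p-values match the published table to 3 decimal places
```

Each row is a discovery-vs-validation comparison; matching the printed
p-values to 3 d.p. pins down the exact test conventions (no continuity
correction; unobserved categories dropped).  The race row is shown for
completeness: the published table used an unspecified Fisher variant that
the Freeman–Halton rule does not reproduce.

Run the full synthetic pipeline (simulate → table one → screen → stability
selection → panel → stepwise → stacking → evaluation):

```bash
$ python analysis/05_multicomponent_models.py --seed 0
retained phenomic variables: ['pheno_00', 'pheno_01', 'pheno_02', 'pheno_03', 'pheno_04']
panel markers: ['prot_0641', 'prot_0737', 'prot_0003', 'prot_0085', 'prot_0529', 'prot_0433', 'prot_0419', 'prot_0913']
Bonferroni-significant proteins: 7
 model  discovery_auc  discovery_ci_low  discovery_ci_high  validation_auc  validation_ci_low  validation_ci_high
     G          0.545             0.491              0.597           0.663              0.572               0.750
     P          0.801             0.757              0.842           0.703              0.605               0.793
    Pr          0.864             0.827              0.899           0.796              0.708               0.871
   P+G          0.802             0.759              0.842           0.718              0.626               0.807
  Pr+G          0.862             0.823              0.899           0.812              0.732               0.883
  Pr+P          0.914             0.885              0.941           0.812              0.725               0.893
Pr+P+G          0.914             0.883              0.940           0.819              0.733               0.894
```

Reading the grid: the genotype alone (G) barely discriminates (discovery
AUC 0.545), the clinical model (P) reaches 0.80, the 8-protein panel (Pr)
0.86, and the combined three-domain model tops the grid at 0.91 in-sample /
0.82 on the frozen-model validation cohort — the qualitative pattern the
method is designed to exhibit.  Seven of the eight selected markers here
are planted signals (`truth.json` records them); `prot_0419` is a false
positive of stability selection at this seed.  `analysis/01`–`04` run the
individual stages with more narrative output.

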