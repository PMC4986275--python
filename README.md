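# musico

From a multigene expression signature to patient-orientated clinical
outcome: penalized Cox survival modelling with honest nested
cross-validation, and systems-level reconstruction of the pathways
associated with the signature's top prognostic genes.

The package is aimed at biostatisticians and computational biologists who
profile a curated gene panel (here: the 24-gene AID/APOBEC cytidine-
deaminase signature) by qPCR in a clinical cohort — such as advanced-stage
serous ovarian carcinoma — and want to (i) quantify how much the signature
adds to clinicopathological risk factors for overall or progression-free
survival, and (ii) map the top-ranked genes onto disease-relevant pathways
via co-expression in public tissue compendia.

## The model

Relative expression is obtained by the ΔΔCt method at amplification
efficiency 2 and analysed on the log2 scale.  For a variable set
*X* (clinical, gene, or combined), a Cox proportional-hazards model is fit
by maximising the penalized Breslow partial log-likelihood

    ℓ(β) − λ Σⱼ βⱼ²   (ridge)   or   ℓ(β) − λ Σⱼ |βⱼ|   (lasso)

with covariates standardised to unit SD during optimisation.  The penalty
weight λ is tuned by minimising the cross-validated partial deviance
(Verweij–van Houwelingen difference construction); an outer leave-one-out
loop repeats the whole development process with each patient held out and
forms the honest cross-validated predictor η̃ᵢ = β̂⁽⁻ⁱ⁾·xᵢ.  Models are
compared by the Schemper–Henderson proportion of explained variation
(PEV), the inverse-probability-of-censoring-weighted concordance index,
and the Wald p of a Cox model on η̃; patients are stratified into
low / intermediate / high risk at the quartiles of η̃.  Variables are
ranked by their standardised coefficients, STDBETA = β̂ⱼ·SD(Xⱼ) — the
log hazard ratio of a one-SD covariate shift.  A correlation-preserving
permutation control (jointly shuffling patient rows of the gene block)
verifies that the algorithm builds no model from pseudo genes.

The network stage selects, per target gene, the tissue samples in the
lowest and highest expression deciles, extracts the top-50 co-expressed
genes by Pearson correlation, pools them into a "mixed" list, tests gene
sets (GMT) by the right-tailed Fisher exact test, and ranks enriched terms
two ways: by mixed-list p with per-target positions (algorithm I), and by
the number of per-target lists sharing the term, ties broken by mixed p
(algorithm II).

Because no patient-level data of the original study are public, a
first-class synthetic-data module generates every input with planted,
recoverable structure (a 186-patient cohort with 29 % deaths, correlated
gene blocks, proportional-hazards outcomes; Ct tables; tissue matrices
with planted co-expression; gene-set collections with one planted set).

## Worked example

```python
import musico as m
from musico.synthetic_data import CohortSpec

cohort = m.generate_cohort(CohortSpec(seed=0))
print(f"cohort: n={len(cohort.outcome)}, deaths={cohort.outcome.n_events} "
      f"({100*cohort.outcome.n_events/len(cohort.outcome):.1f}%)")

res = m.fit_univariate_cox(cohort.expression_log2["ID3"], cohort.outcome)
print(f"univariate ID3: HR={res.hr:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"p={res.p:.4f}")

X = cohort.model_matrix("combined")
tuning = m.tune_lambda_loocv(X, cohort.outcome, "ridge", cv=10, seed=0)
fit = m.fit_penalized_cox(X, cohort.outcome, "ridge", tuning.lam_opt)
ranking = m.rank_variables(fit, cohort.outcome)
print(ranking[["rank", "beta", "HR", "STDBETA", "selected"]].head(6))
```

prints

```
cohort: n=186, deaths=54 (29.0%)
univariate ID3: HR=1.43 (95% CI 1.16-1.77), p=0.0008
          rank      beta        HR   STDBETA  selected
ID3          1  0.194593  1.214817  0.279514      True
age          2  0.021069  1.021293  0.225454      True
AICDA        3  0.140549  1.150906  0.207926      True
PAX5         4 -0.105362  0.899999 -0.158767      True
APOBEC3G     5 -0.097460  0.907138 -0.148847     False
PTPRC        6  0.101661  1.107008  0.145114     False
```

The cohort realises the configured 29 % event fraction; ID3 carries the
planted adverse effect (higher expression, higher hazard) and tops the
ranking of the combined ridge model; `selected` marks variables passing
the |STDBETA| ≥ 0.15 target-gene cut-point.  Shrinkage pulls each HR
toward 1, so the penalized HRs are deliberately closer to 1 than the
univariate one.

The full pipeline (preprocessing → three models × two penalties →
evaluation, stratification and permutation control → network
reconstruction) runs from one call:

```sh
musico run --seed 0 --out results/
```

writing `report.json`, a `model_comparison.tsv` of PEV / c-index / p per
model (unavailable
models render "n.a."), per-model rankings and risk strata, KM curves,
permutation replicates and the enrichment/ranking tables, plus a checksum
manifest.

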