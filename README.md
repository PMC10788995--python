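# lncpairsig

Rank-based lncRNA-pair prognostic signatures for hepatocellular carcinoma
(HCC).

Most expression signatures score patients from absolute transcript
abundances, which makes them fragile across platforms and batches. This
package implements the alternative: binary *pair* features
`X(A,B,s) = 1 iff expr(A,s) > expr(B,s)` over vascular-invasion-related,
differentially expressed lncRNAs. Within-sample comparisons are invariant to
any per-sample monotone normalization, so the resulting risk score

    score(s) = exp( Σᵢ βᵢ · xᵢ(s) )

needs no batch correction. The pipeline covers the whole analysis: gene-set
co-expression screening, moderated-t differential expression, the 0-or-1 pair
matrix with its 20% validity filter, univariate Cox + LASSO-Cox signature
selection, IPCW time-dependent ROC with Youden-optimal cutoff, high/low-risk
stratification with Kaplan–Meier / log-rank / multivariate Cox validation,
and downstream association tests (immune checkpoints, EMT genes, immune
subtypes, drug IC50s). The published 5-pair HCC signature ships as a constant
(`published_signature()`), and a seeded synthetic-cohort generator with
planted ground truth makes every stage testable end to end.

It is aimed at computational biologists building or auditing survival
signatures from bulk RNA-seq cohorts (TCGA-style matrices plus clinical
follow-up).

## Worked example

Run the full pipeline on the default synthetic cohort (365 tumor / 50 normal
samples, 97 linked lncRNAs, 14 planted DElncRNAs, planted 5-pair signature
with the published coefficients):

```python
from lncpairsig import (
    align_cohort, build_pair_matrix, coexpression_screen, compute_risk_score,
    filter_valid_pairs, fit_lasso_cox, logrank_test, moderated_de,
    optimal_cutoff, simulate_cohort, stratify, survival_roc,
    univariate_cox_screen,
)

cohort = simulate_cohort(seed=1)
expr, clin = cohort.expr, cohort.clinical

tumors = expr.tumor_samples
hits = coexpression_screen(
    expr.lncrnas().subset_samples(tumors),
    expr.subset_genes(list(cohort.geneset.members)).subset_samples(tumors),
)
de = moderated_de(expr.subset_genes([h.lnc_id for h in hits]))
de_ids = [r.gene_id for r in de if r.significant]

expr_t, clin = align_cohort(expr, clin)
pm = filter_valid_pairs(build_pair_matrix(expr_t.subset_genes(de_ids)))
keep = [f.term for f in univariate_cox_screen(pm, clin) if f.significant]
model = fit_lasso_cox(pm.subset_pairs(keep), clin, seed=1)

scores = compute_risk_score(model, pm)
roc = survival_roc(scores, clin, horizon=365)
strat = stratify(scores, optimal_cutoff(roc))
chi2, p = logrank_test(strat, clin)
print(len(hits), len(de_ids), len(pm.pair_ids), len(keep), len(model.pairs))
print(f"AUC={roc.auc:.3f} cutoff={strat.cutoff:.3f} "
      f"high/low={strat.n_high}/{strat.n_low} logrank p={p:.2g}")
```

prints

```
97 14 91 20 8
AUC=0.712 cutoff=1.195 high/low=100/265 logrank p=3.7e-14
```

i.e. the screen keeps 97 vascular-invasion lncRNAs, all 14 planted DElncRNAs
pass the differential-expression gates, their 91 pairs all survive the
validity filter, 20 are prognostic in univariate Cox, and LASSO-Cox retains
an 8-pair signature whose score separates survival strongly (1-year AUC 0.71;
the two risk groups differ at log-rank p ≈ 4 × 10⁻¹⁴).

To score any cohort with the published 5-pair model instead:

```python
from lncpairsig import published_signature
model = published_signature()        # 5 pairs, coefficients 0.3776 ... 0.4547
scores = compute_risk_score(model, pm_with_those_pairs)
```

The same stages are available as a CLI
(`lncpairsig simulate | screen | pairs | signature | evaluate | associate`);
each subcommand writes plain TSV/YAML and `--help` lists every threshold.

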