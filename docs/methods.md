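# Methods

## The model

`lncpairsig` implements a prognostic-signature pipeline for hepatocellular
carcinoma built on *rank-based gene-pair features*. For two lncRNAs A and B and
a sample s, the pair indicator is

    X(A, B, s) = 1  if expr(A, s) > expr(B, s),  else 0  (ties score 0).

Because X compares two genes within the same sample, it is invariant to any
strictly increasing per-sample transform of the expression values. A signature
of such indicators therefore needs no absolute expression levels, no
cross-platform normalization and no batch correction — this invariance is the
method's central claim, and it is enforced by property tests (pair matrix,
risk scores, time-dependent AUC and downstream rank tests are bit-identical
under per-sample monotone warping).

The full chain:

1. **Co-expression screen.** lncRNAs correlated with at least one member of a
   curated vascular-invasion gene set (default Pearson r > 0.4, P < 0.001 on
   log2(x+1)) are retained. The screen is computed within tumor samples: the
   gene set describes tumor biology, and tumor-only expression shifts of
   individual lncRNAs would otherwise dilute the correlation with group
   variance unrelated to the shared activity. The threshold is signed
   (`r > r_min`) following the stated rule; `use_abs` switches to `|r| > r_min`.
2. **Moderated differential expression** (tumor vs normal, log2(x+1)).
   Gene-wise residual variances s² (pooled, d = n_t + n_n − 2 df) are shrunk
   toward an empirical-Bayes prior s₀² with d₀ prior df fitted by moment
   matching on log s² (digamma/trigamma method; no positive trigamma solution
   ⇒ d₀ = ∞, full shrinkage). The moderated t uses the posterior variance
   (d₀s₀² + ds²)/(d₀ + d) and a t reference with d₀ + d df; d₀ = 0 recovers
   the ordinary two-sample t exactly. Genes pass at BH-FDR < 0.05 and
   |log2FC| > 2 (a signed up-only gate is available; in the cohort this
   pipeline targets, all hits were up-regulated).
3. **Pair matrix.** All K(K−1)/2 unordered pairs of DElncRNAs, oriented by
   input gene order, computed on tumor samples. The validity filter keeps a
   pair iff its fraction of ones lies strictly inside (0.2, 0.8): a pair whose
   indicator is (nearly) constant carries no information. Strictness at the
   boundary is not determined by the method's description; the strict reading
   is used and exact-boundary pairs are logged.
4. **Signature selection.** Univariate Cox proportional hazards per pair
   (Efron ties, Wald inference; gate p < 0.05), then L1-penalized Cox over the
   survivors. λ is chosen at the minimum of the cross-validated partial-
   likelihood deviance (10 folds stratified by event status, seeded); the
   deviance of a held-out fold is −2 × its Breslow log partial likelihood
   under the training coefficients. Indicators enter unstandardized so the
   coefficients live on the 0/1 scale of the published model. λ_min rather
   than the 1-SE rule: the published signature retains 5 of 12 screened pairs,
   consistent with minimum-deviance selection.
5. **Risk score and stratification.** score(s) = exp(Σᵢ βᵢ xᵢ(s)); 1 for an
   all-zero indicator sample. The time-dependent ROC at a horizon τ (default
   365 days) uses the cumulative-case / dynamic-control estimator with
   inverse-probability-of-censoring weights from the Kaplan–Meier estimate of
   the censoring distribution; with no censoring it reduces exactly to the
   binary ROC of the event-by-τ indicator. The cutoff maximizes Youden's
   J = sens + spec − 1 (the usual operationalization of the "highest
   inflection point"); ties resolve to the larger threshold, which assigns
   fewer patients to the high-risk group, and scores exactly at the cutoff
   are low-risk. The horizon behind the published cutoff (1.395) is not
   recorded anywhere; it is the single most consequential free parameter and
   is surfaced in the CLI (`--horizon`) and logs.
6. **Validation and associations.** Kaplan–Meier curves and the two-group
   log-rank test; univariate and multivariate Cox with ordinal-encoded
   clinical covariates (grade G1–G4 → 1–4, stage I–IV → 1–4, male = 1);
   AUC comparison of the risk score against clinical features at a shared
   horizon; high-vs-low comparisons of checkpoint/EMT/stemness gene
   expression and of drug IC50s by the two-sample Wilcoxon rank-sum test
   (the original description says "signed-rank", which is impossible for
   unpaired groups — rank-sum is the only defensible reading); Spearman or
   Pearson score–feature correlations; Pearson χ² for clinical proportions;
   Kruskal–Wallis across immune subtypes with BH-adjusted pairwise rank-sum
   follow-ups, after dropping levels with fewer than 3 samples (the C5/C6
   immune classes are absent from HCC cohorts).

## Numerical choices

* Cox fits use lifelines (Newton–Raphson, Efron tie handling); the L1 path
  uses scikit-survival's coxnet. The held-out deviance scorer is in-package
  because no coxnet cross-validation scorer ships with scikit-survival.
* The rank-sum test is exact by full enumeration of label assignments when
  n₁ + n₂ ≤ 20 (two-sided p as the probability of a rank-sum deviation at
  least as large as observed — correct under ties, where the null is not
  symmetric), and otherwise uses the normal approximation with tie-corrected
  variance and a 0.5 continuity correction.
* Correlation p-values use the exact t transform for Pearson and the same
  transform on mid-ranks for Spearman (large-sample approximation); no
  resampling anywhere, so every result is deterministic.
* Perfectly collinear covariates are detected by a rank check before the
  multivariate Cox fit and reported by name; non-converging univariate fits
  are returned flagged and never counted as significant.
* Degenerate inputs fail loudly: empty pair matrices, groups without events,
  stratifications with an empty arm, constant vectors in correlations.

## The synthetic cohort generator

Real cohorts of this design (tumor/normal RNA-seq with survival) cannot ship
with the package, so `simulate` generates cohorts with the statistical
structure the analysis assumes, with known ground truth:

* Per sample, a latent vascular-invasion activity v ~ N(0, 1). Gene-set
  members and "linked" lncRNAs have log2 expression μ_g + f·v + √(1−f²)·ε
  with loading f (`factor_loading`, default 0.7), so the Pearson correlation
  between a linked lncRNA and a member is f² ≈ 0.49 on the log scale — above
  the 0.4 screen threshold but not trivially so. Unlinked genes are pure
  noise. Expression is exponentiated (log-normal, strictly positive).
* The first `n_de_lnc` linked lncRNAs (default 14, the number of DElncRNAs
  the pipeline's target cohort yielded) gain `de_log2fc` (default 3) in tumor
  samples only. Planted DElncRNAs share one baseline mean so their pairwise
  indicators stay balanced and survive the validity filter.
* Overall survival of tumor samples is exponential with hazard
  h₀·exp(Σ β_p x_p), where x_p are indicators of planted pairs. The default
  planted signature copies the published 5-pair topology (one lncRNA in three
  pairs, another in two) with the published coefficients 0.3776, −0.3176,
  −0.3402, −0.3572, 0.4547. h₀ = 10⁻³/day puts median survival near two
  years. Censoring is an independent exponential whose rate is solved
  analytically so the expected censored fraction equals `censor_rate`
  (default 0.6, typical of TCGA-like follow-up).
* Cohort size defaults to 365 tumor and 50 normal samples; 500 lncRNAs of
  which 97 are linked (the screening counts of the target cohort); clinical
  covariates from fixed categorical distributions (male-skewed sex, G2/G3
  dominated grade, early-stage dominated stage, immune subtypes C1–C4 only);
  an IC50 matrix of 14 drugs of which half depend linearly on the true log
  risk (noise SD 0.5 against unit signal SD).

What the generator does **not** emulate: count-level sampling noise,
library-size or batch effects, correlated lncRNA–lncRNA structure beyond the
single shared factor, non-proportional hazards, informative censoring, and
missing clinical fields. Passing tests therefore demonstrate correctness of
the estimators and selection machinery under the model's own assumptions, not
robustness to the full messiness of real RNA-seq cohorts.

## Problem sizes used in tests

The test suite and acceptance script size their simulations to what the
statistics require rather than to the largest cohort available: estimator
identities use 4–30-sample fixtures with exhaustive oracles; calibration
checks use n = 2000 (AUC) and 200 repetitions (type-I error); recovery checks
use n = 300–400 over 20–50 seeds, where binomial/SE bounds make the asserted
margins comfortable.

## Known limitations

* With the published effect sizes (|β| ≤ 0.45) and n = 365, LASSO selection
  is not expected to recover the planted pairs exactly — correlated surrogate
  pairs (sharing a lncRNA) are routinely selected instead. Selection
  consistency is demonstrated at β = 0.8, where it holds in ≥ 80% of cohorts.
* The published 5-pair model can be applied to any cohort via
  `published_signature()`, but reproducing the published patient split
  (187/178 at cutoff 1.395) requires the original cohort's expression and
  follow-up, which the package does not download.
* The univariate screen's p < 0.05 gate, the fold count, the CV seed and the
  ROC horizon are all unrecorded in the method this package re-implements;
  the defaults here are explicit, logged choices.
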