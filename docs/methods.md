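# Methods

This note documents the statistical models and procedures implemented in
osteomir, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions used at
edge cases.

## Expression spaces and transforms

Every matrix carries a declared value space (`counts`, `log2norm`, `Ct`,
`beta`, `M`) and each operation enforces the space it expects.

* **Size-factor normalization** uses the classical median-of-ratios
  estimator: the reference set is the features with strictly positive counts
  in every sample; sample *j*'s size factor is the median over reference
  features of count<sub>ij</sub>/geomean<sub>i</sub>. Output is
  log2(count/s<sub>j</sub> + 1). The +1 pseudocount keeps zero counts finite;
  it is a package choice, as the log transform alone does not define one.
  There is deliberately no pseudo-reference fallback when no feature is
  positive everywhere — that situation signals data that should not be
  normalized this way, so it errors instead.
* **2^−ΔCt** converts qRT-PCR cycle thresholds to linear relative expression
  against a user-named reference feature. The endogenous control is always
  supplied by the caller; the package does not guess one.
* **β→M** is M = log2(β/(1−β)) with β clamped to [ε, 1−ε] (default ε = 1e−6)
  so boundary β values stay finite. All methylation testing happens in M
  space because β values are heteroskedastic near 0 and 1.
* **Variance filter** retains the ⌈(1−f)·F⌉ highest-variance features
  (unbiased sample variance), breaking variance ties by lexicographic
  feature id so results are reproducible. The gene-set pipeline applies
  f = 0.20 before expansive-tier analysis only; methylation robustness
  checks use f = 0.50.
* **Length filter** removes transcripts with annotated length strictly below
  the threshold (default 200 bases), so a 200-base transcript is kept.

## Sequence mapping

A probe maps to a reference mature miRNA iff some contiguous run of at least
k = 18 bases (after uppercasing and U→T) occurs exactly in the reference, at
any offset in either sequence. Matching at any offset rather than only from
probe position 0 is the more permissive reading and is flagged here as a
design choice; some discovery-platform probes are exactly 18 bases, where
the two readings coincide. Probes matching several references are reported
against all of them and flagged ambiguous — downstream profile construction
uses only unambiguous matches.

## Survival machinery

* **Kaplan–Meier**: product-limit estimator (via lifelines); the median is
  the earliest observed time with S(t) ≤ 0.5 and is reported as the explicit
  token `"not reached"` (never infinity) when the curve stays above 0.5.
* **Log-rank**: implemented directly so that stratification is supported —
  observed-minus-expected death counts and their hypergeometric covariance
  are accumulated per stratum and summed before the quadratic form, with one
  group dropped to make the covariance invertible (pseudo-inverse guards
  degenerate tables). The unstratified case is verified in the test suite
  against an independent implementation (lifelines) to 1e−9.
* **Cox regression**: lifelines' partial-likelihood maximization with Efron
  tie handling — the default of the mainstream survival software this kind
  of analysis is run with. Constant covariates and separation produce
  informative errors instead of silent non-convergence.
* **Score test at β = 0**: gene-level screening needs tens of thousands of
  univariate p-values, so the Rao score test is computed in closed form at
  the null (Efron tie adjustment included). For a binary covariate without
  ties it coincides with the two-group log-rank test, which the suite checks
  to 1e−6. Constant genes carry no information and are recorded with p = 1
  and a flag rather than an error, because a screen should not die on a flat
  gene.

## Risk models

* **Signed-average score**: features are z-scored (unbiased SD) before
  weighting by ±1 and averaging, so that a single high-variance feature
  cannot dominate the index; raw-scale averaging is available via
  `standardize=False`. Dichotomization is at the within-cohort median, and
  samples exactly at the median go to the low-score group — a deterministic,
  documented tie rule. Missing profile features are dropped with a warning
  and recorded in the result.
* **Clustering**: average linkage on 1 − Pearson distance between sample
  vectors over the profile features (samples are clustered; features are
  not co-clustered, since only the sample partition feeds survival
  analysis). Note that centered correlation is invariant to per-sample
  additive shifts: groups separated only in overall level are invisible to
  it; separation must live in the expression pattern.
* **R-index**: each perturbation adds i.i.d. Gaussian noise with SD =
  factor × pooled within-feature SD (root mean of per-feature variances),
  reclusters at the same k, and measures the fraction of originally
  co-clustered pairs still together; R is the mean over perturbations. The
  default factor 0.5 and 50 perturbations are package defaults — the
  perturbation variance of the original reproducibility procedure is not
  fully specified in the source literature — and both are exposed. Factor 0
  provably gives R = 1 because clustering is deterministic.
* **Composite classifier**: (low risk, optimal necrosis) → very favorable;
  (high, suboptimal) → very unfavorable; the two mixed cells → intermediate.
  The rule is a total function on exactly four cells and is tested
  exhaustively.
* **Concordance**: χ² without continuity correction feeds Cramér's V
  (V = √(χ²/(n·(min(r,c)−1))), the standard convention for V), while
  significance in 2×2 tables is reported from Fisher's exact test. A
  single-category labelling leaves V undefined (NaN), not zero.

## Gene-set survival analysis

LS = mean(−ln p) and KS = max<sub>i</sub>(i/k − p<sub>(i)</sub>) (floored at
0, one-sided toward small p — only enrichment in the significant direction
counts). The permutation null draws random gene sets of the same size
without replacement from all measured genes, and
p = (1 + #{null ≥ observed})/(1 + n_perm), so permutation p-values are never
zero. Gene sampling (rather than phenotype permutation) matches the
functional-class-scoring convention; it conditions on the observed per-gene
p-value landscape, which also means a universe saturated with signal raises
the null bar — a property, not a bug, for specificity controls. Sets with
fewer than five usable genes are reported "too small" instead of being
scored. The random-set specificity control scores 10 random sets of 44 genes
(the size of the union of the 5-miRNA target lists) through the identical
machinery.

EASE enrichment uses the one-sided hypergeometric upper tail with the
overlap cell decremented by one, so an overlap of 0 or 1 can never be
significant; BH step-up q-values are computed across pathways.

## Methylation analysis

Welch (unequal-variance) t-tests per probe in M space; the headline count of
differential probes uses unadjusted p < 0.05 with BH q reported alongside
for transparency. miRNA–CpG association uses Spearman rank correlation with
per-miRNA summaries (count significant, median and range of significant
rho). Methylation-based stratification reuses the clustering/R-index/
log-rank machinery and reruns after dropping the 50% least-variant probes,
reporting the label-matched partition agreement as the robustness measure.

## Pharmacogenomic screen

Stage 1 keeps associations with |coefficient| > 0.25 **and** p < 0.001, both
strict, so a coefficient of exactly 0.25 fails; relaxed mode uses 0.15/0.05.
Stage 2 requires ≥ 3 distinct genes hit in the broad (22-miRNA) network and
≥ 1 in the core (5-miRNA) network — hits are counted per distinct gene, not
per experiment row, because association tables are per-experiment. Stage 3
takes each drug's median IC50 (midpoint interpolation) over its available
osteosarcoma cell lines and admits drugs at or below the reference drug's
median (cisplatin by default) — "at or below" because the reference defines
the minimum acceptable potency, so a tie passes. Drugs measured in ≤ 3 cell
lines are flagged limited-evidence; drugs with no sensitivity data are
flagged and excluded from stage 3 rather than failed silently. Because each
stage only removes drugs, loosening any threshold can never shrink the
final set (property-tested on random tables).

The package ships the published per-drug screen summary (median IC50 and
median regression coefficient for 19 candidate drugs plus methotrexate,
etoposide and cisplatin as comparators) and can replay the final selection
stage on it; the three comparators enter only as reference rows.

## Synthetic cohorts

The generator emulates the joint structure the analyses assume:

* miRNA log2 expression: per-feature baseline ~ N(8, 1), unit noise SD;
  5 profile features and 45 noise features by default.
* Survival: exponential (constant baseline hazard) proportional-hazards
  times with per-sample hazard h₀·exp(Σ β<sub>g</sub> z<sub>gs</sub>);
  defaults β = 0.5 per profile feature and h₀ = 0.01 events/month (median
  ≈ 70 months at zero risk, matching the scale of osteosarcoma RFS), with
  independent uniform censoring on [0, 120] months. Exponential rather than
  Weibull keeps sampling closed-form while satisfying the Cox model exactly.
* Clinical covariates: metastasis ~ Bernoulli(0.25) (the observed cohort
  fraction scale); necrosis is the binary class {optimal, suboptimal} with
  log-odds of suboptimal = 1.0 × centered latent risk. Necrosis is never
  simulated as a percentage, only as the dichotomized class.
* mRNA targets: 10 expansive targets per profile miRNA (first 3
  restrictive), each −0.5-correlated with its regulator, plus 100 null
  background genes.
* Methylation: 9 CpGs per profile miRNA whose M-values correlate with the
  regulator at Pearson 0.35 (Gaussian copula; the implied Spearman ≈ 0.336);
  β values are the inverse-logit2 of M.
* Drug tables: 3 of 30 drugs are planted active — strong associations
  (|coef| ∈ [0.3, 0.6], p < 10⁻³·⁵) with ≥ 3 broad-network genes including a
  core-network gene, and cell-line IC50s drawn well below cisplatin's —
  while inert drugs fail stage 1 by construction (sub-threshold coefficient
  or non-significant p).

Default sizes (150 samples; the grid of table sizes above) were chosen so
that planted effects are recoverable with high power while whole-suite
simulations stay cheap. No published per-miRNA effect-size estimates exist
for these profiles, so the defaults are set for testability at a realistic
cohort scale rather than to mimic a particular dataset.

All randomness flows from one seed through deterministically spawned
substreams, so cohorts are bit-identical for a fixed seed.

**What passing tests do not show**: the generator draws Gaussian
log-expression without sequencing noise, batch effects, probe chemistry, or
library-size artifacts; censoring is uniform and non-informative; metastasis
is independent of risk. Power and calibration results on these cohorts
demonstrate correctness of the machinery, not expected performance on real
cohorts with heavier tails, confounding and platform effects.

## Numerical conventions

* p-values of exactly 0 entering LS/KS are clamped to the machine minimum
  with a warning (−ln 0 is infinite).
* Permutation p-values use the add-one rule and therefore live on
  {1/(1+B), …, 1}.
* Median survival "not reached" propagates as a string token, never ∞.
* Matrix TSVs round-trip exactly (full float repr on write); pipeline JSON
  reports format floats at 10 significant digits.
* Cluster merge ties follow SciPy's deterministic ordering; merge-distance
  ties have measure zero for continuous data and do not affect the oracle
  comparisons in the test suite.

## Known limitations

* No fully parametric multivariate prediction model and no optimal-cutpoint
  search — both deliberately out of scope; the signed-average/median-split
  design is the point.
* No time-varying covariates, competing risks or interval censoring.
* Pathway enrichment runs on user-supplied GMT collections; no live
  database queries.
* The stratified log-rank test assumes each stratum contributes
  independently; very small strata contribute little information and can
  make the covariance nearly singular (handled via pseudo-inverse).
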