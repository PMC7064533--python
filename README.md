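# osteomir

Prognostic-biomarker analysis for osteosarcoma miRNA signatures: risk
scoring, survival stratification, gene-set and methylation analysis, and a
staged pharmacogenomic drug screen — packaged as a tested, reusable Python
pipeline with a synthetic-cohort generator for validation.

## The problem

Osteosarcoma outcome prediction currently rests on pathologic necrosis after
neoadjuvant MAP chemotherapy, which is semi-quantitative and only available
after treatment has started. Small microRNA profiles measured in the
pre-chemotherapy diagnostic biopsy — notably a 5-miRNA profile and a broader
22-miRNA profile, mostly from the imprinted 14q32 locus — are candidate
molecular markers of recurrence-free survival (RFS). Validating such profiles
across cohorts and assay platforms requires a specific chain of methods, which
this package implements:

* **Cross-platform signature mapping.** Probe sequences from the discovery
  platform are carried to a new assay only when a perfect contiguous match of
  ≥ 18 bases exists against the mature miRNA reference sequence (U/T and
  case-insensitive, ambiguous matches flagged).
* **Signed-average risk score.** For a profile *G* with direction weights
  *w<sub>g</sub>* ∈ {+1, −1} (the sign of each miRNA's hazard ratio in the
  discovery data), each sample *s* gets
  *S<sub>s</sub>* = (1/|G|) Σ<sub>g</sub> *w<sub>g</sub>* *x̃<sub>gs</sub>*,
  with *x̃* the per-feature z-score. Cohorts are dichotomized at the median
  score. No coefficients are fitted, so nothing can overfit.
* **Unsupervised stratification with reproducibility.** Samples are clustered
  by average linkage on centered-correlation distance (1 − Pearson), and
  partition stability is quantified by the R-index: the fraction of
  co-clustered sample pairs that remain co-clustered after Gaussian noise
  perturbation and reclustering.
* **Survival testing.** Kaplan–Meier curves with explicit "not reached"
  medians, plain and stratified log-rank tests, and Cox proportional-hazards
  regression (Efron ties) for multivariable adjustment.
* **Composite classification.** Risk group × necrosis class →
  {very favorable, intermediate, very unfavorable}; concordance between
  classifications is measured with χ², Fisher's exact test and Cramér's V.
* **LS/KS gene-set survival tests.** A miRNA's mRNA target set is scored by
  LS = mean(−ln p) and KS = max(i/k − p<sub>(i)</sub>) over per-gene Cox
  score-test p-values, with permutation p-values from random gene sets of
  equal size, plus EASE-penalized hypergeometric pathway enrichment.
* **Methylation analysis.** β→M conversion, per-probe Welch t-tests between
  expression-defined groups with BH FDR, Spearman miRNA–CpG correlation, and
  methylation-based clustering with a half-variance-filter robustness check.
* **Staged pharmacogenomic screen.** Gene–drug associations are filtered at
  |coefficient| > 0.25 and p < 0.001 (relaxed mode 0.15/0.05), drugs must hit
  ≥ 3 genes of the 22-miRNA network and ≥ 1 of the 5-miRNA network, and
  surviving drugs are ranked by median IC50 across osteosarcoma cell lines
  with cisplatin's median as the admission threshold.

A synthetic-cohort generator (`osteomir.simulate`) produces all the tables
the pipeline consumes — expression, clinical, methylation, target-map and
drug tables — with known planted structure, so every stage can be tested for
parameter recovery and calibration.

## Worked example

Run the whole pipeline on a simulated 150-patient cohort:

```bash
osteomir run-all --seed 1 --out demo-run
```

prints (abridged):

```json
{
  "seed": 1,
  "n_samples": 150,
  "logrank_p_signed_average": 6.319716807145294e-06,
  "r_index_mirna_profile": 0.9752584799564664,
  "n_differential_cpgs": 19,
  "n_final_drugs": 3,
  "planted_drugs": ["drug-01", "drug-02", "drug-03"]
}
```

Reading this: the signed-average median split separates recurrence-free
survival decisively (log-rank p ≈ 6e-6 — the cohort was simulated with five
profile miRNAs each carrying log-hazard 0.5), the miRNA-profile clustering is
highly reproducible (R ≈ 0.98), 19 of the 45 annotated CpG probes are
differentially methylated between the risk groups, and the drug screen's
final list is exactly the three planted active drugs. Per-stage TSV outputs
(risk scores, cluster labels, composite groups, gene-set results, the full
drug report) land in `demo-run/`.

The same stages are available individually (`osteomir simulate`, `score`,
`cluster`, `survival`, `composite`, `gsa`, `methyl`, `pharmaco`,
`map-signature`) on user-supplied TSV/FASTA inputs.

The published drug-screen summary shipped with the package can be replayed
directly:

```python
>>> from osteomir import published_final_selection
>>> len(published_final_selection())
19
```

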