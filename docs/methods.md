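# Methods

This note documents the statistical procedures implemented in `mrbiom`,
the choices made where the design was genuinely open, and what the
synthetic cohorts can and cannot show about real data.

## Differential-expression screen

Features are compared between case and control groups on the
log2(value + pseudocount) scale. The fold change is the difference of
group means on that scale; the test is a two-sided Welch two-sample
t-test; multiplicity is controlled with Benjamini–Hochberg. A feature
is retained when `padj < padj_max` (strict) and `|log2fc| >= lfc_min`
(inclusive). Defaults per class: mRNA (0.01, 1), miRNA (0.01, 1),
lncRNA (0.05, 1); pseudocount 1.0, since zeros are routine in RNA-seq
derived tables.

The Welch test stands in for moderated-variance approaches: the
downstream algorithm consumes only the list of DE features and their
directions, so the screen is an exchangeable interface — a moderated
variant can be substituted without touching anything downstream.
Testing is unpaired even when the discovery cohort is paired; a
within-patient variant is deliberately out of scope. Features constant
in both groups get p = 1 by convention.

## Information scoring

**Correlation blocks.** Pearson correlations between every DE mRNA and
every DE miRNA (matrix M, N×J) and every DE lncRNA (matrix L, N×K) are
computed across the discovery samples, with two-sided p-values from the
exact t reference distribution with n − 2 degrees of freedom. The
vectorised block computation is tested cell-by-cell against the scalar
`scipy.stats.pearsonr` oracle to 1e−12. Zero-variance expression rows
produce "no significant correlation" rather than an error.

**Information rates.** Row x of each block is reduced to its entries
with p < alpha (default 0.05, unadjusted; an adjusted option exists but
is off by default since the procedure is defined on raw significance).
Each retained magnitude |r| is divided by the row's sum of retained
magnitudes. Absolute values are used because a raw negative coefficient
would produce a negative rate and an undefined logarithm, while |r|
preserves the strength of the coupling; the sign of a coexpression
relationship carries no weight in this score.

**Entropy, PPI information, total.** S_RNA(x) is the Shannon entropy
(bits) of the two rate vectors summed; an empty or singleton vector
contributes 0. S_PPI(x) = 1 + Σ cs over edges incident to x's symbol
*within the DE-mRNA symbol set*; unmapped or isolated symbols score
exactly 1. Connection scores live on [0, 1]; STRING's 0–1000 integer
exports are divided by 1000 at read time. No confidence cutoff is
applied to PPI edges by default. S(x) sums the two components after
dividing each by its maximum, so S ∈ (0, 2] and at least one mRNA
attains 1 on each non-degenerate component.

**Knee selection.** The descending S(x) curve is scanned for its
largest single consecutive drop; Q is the 1-based index of the point
before that drop, floored at `q_min` (default 10). The published
procedure chooses Q visually from the curve; the largest-drop rule is
the simplest reproducible formalisation. A flat curve falls back to
`q_min` with a warning, and a fixed-Q override is available. Ties in
S(x) break lexicographically by feature id so runs are deterministic.

## Cancer-related factor (CF)

CF of a sample is mean log2(up-biomarker expression + pseudocount)
divided by the same mean over down-biomarkers. Up/down membership comes
from the DE screen's direction field. Classification is strictly
`CF > threshold` → positive; equality is negative.

**Threshold calibration.** n case and n control samples are merged into
n synthetic boundary samples — per biomarker m and sample i,
S_m(i) = (S_tm(i) + S_nm(i)·scale)/2 — and the threshold is the
geometric mean of the n boundary CF values. Two scale conventions are
implemented:

* `per_sample` (default): scale_i = Σ_m S_tm(i) / Σ_m S_nm(i), a
  library-size-style factor per combined sample. The control partner is
  raised to the case sample's overall biomarker mass while keeping its
  own up/down contrast, so the combined sample lies between the classes
  and the geometric-mean threshold discriminates them. Under planted
  4-fold shifts the calibrated threshold lands strictly between the
  per-class mean CFs and held-out balanced accuracy exceeds 0.95.
* `per_biomarker`: scale_m = Σ_i S_tm(i) / Σ_i S_nm(i), the biomarker's
  own fold change. Rescaling each control row by its own fold change
  reconstructs a case-level row (exactly so when the rows are
  proportional — a property the tests pin down), so the threshold
  coincides with the centre of the case CF distribution and cannot
  separate the classes. The mode is retained because it is the most
  literal reading of the construction's printed index structure, but it
  is not recommended and not the default; the default is the reading
  under which the construction achieves its stated purpose of placing
  the threshold at the class boundary.

Both conventions coincide on single-biomarker profiles and are
invariant to a common rescaling of the control profile. Thresholds
calibrated on disjoint pairings of the same cohort agree within 10%.

## Classifier cross-validation

The case group is downsampled uniformly without replacement (default
28 cases / 22 controls, mirroring a typical tumour:normal imbalance)
and a plug-in classifier (random forest, RBF-SVM or Gaussian naive
Bayes, scikit-learn defaults, no tuning — the evaluation targets the
biomarkers, not the classifier) is scored with stratified 5-fold
cross-validation. Per-fold accuracy/sensitivity/specificity come from
the confusion counts; report averages are plain arithmetic means of
fold values. SVM and NB see standardised features.

## Survival pipeline

Patients with missing follow-up or survival below 30 days are dropped
(deaths that early are unlikely to be disease-driven). Each biomarker
is screened with a univariate Cox proportional-hazards fit (lifelines,
Breslow ties); those with Wald p < 0.05 enter a joint multivariate fit,
the covariates significant there (Wald p < 0.05) are refit together,
and the refit coefficients W define the risk score Risk = Σ W·Exp.
With a single screened covariate this chain reduces exactly to the
univariate fit. Expression enters the hazard model on the log2 scale —
the scale on which expression effects are conventionally modelled and
on which the synthetic generator plants its coefficients.

Patients are split at the median risk score (strict `>` → high risk;
for odd n the median holder falls in the low group — the only rule
producing a 134/135 split of 269 patients). Groups are compared with
Kaplan–Meier curves and the two-group log-rank test. The time-dependent
ROC at horizon t uses the Kaplan–Meier estimator of case/control status
probabilities within marker strata (the survivalROC-style construction):
sens(c) = P(X>c)(1 − S_{X>c}(t))/(1 − S(t)),
spec(c) = P(X≤c)·S_{X≤c}(t)/S(t), integrated by trapezoid over all
observed cutoffs. With no censoring it agrees with the IPCW
cumulative/dynamic AUC to ~0.001 (cross-checked against scikit-survival
in the tests). The default horizon is the cohort's median follow-up.

## Synthetic cohorts

The generator emulates a two-condition tumour study: a paired 20+20
discovery cohort and an unpaired 120+15 evaluation cohort drawn from
one frozen feature structure, so models discovered on one cohort apply
to the other. Defaults: 150 mRNAs / 50 miRNAs / 300 lncRNAs with
30 / 25 / 125 DE features (roughly the published 170/52/623 DE sets,
scaled down so the desk-scale suite runs in seconds), ±2 log2 units of
DE shift (4-fold), unit log2 noise, 75% of DE features shifted up.

Ten DE mRNAs are hubs: each shares a latent Gaussian factor with 15 DE
miRNA/lncRNA partners at loading √0.8, giving hub–partner correlation
≈ 0.8; partners inherit their hub's DE direction so the case shift
reinforces rather than cancels the coupling in pooled-sample
correlations. The PPI graph wires each hub to ≥ 10 DE mRNAs against a
Poisson background of mean degree ≈ 2, with scores uniform on
[0.4, 0.95]. Survival: the first four hubs carry true log-hazard
coefficients (−0.8, 0.6, −0.7, 0.5) per unit log2 expression — signs
alternating as in published four-gene risk models, magnitudes large
enough that ±30% recovery is statistically resolvable at n = 500 —
with exponential event times (median ≈ 600 days at the baseline) and
uniform censoring bisected to a 30% target.

Expression is log-normal (Gaussian on log2 scale, exponentiated):
the pipeline consumes Pearson correlations and log-scale contrasts,
for which the log-scale Gaussian structure is the relevant one.
The generator does not attempt negative-binomial count marginals,
batch effects, library-size artefacts, tumour purity gradients or
correlated censoring; passing recovery tests therefore demonstrates
algorithmic correctness under the planted model, not robustness to
those real-data complications.

Everything is deterministic under the config seed. When a knee
selection happens to contain only one DE direction (possible at small
Q with random planted directions), CF evaluation widens the panel to
the full DE-mRNA set, since CF is undefined without both sets.

## Numerical conventions

* p-values for correlations: exact t transform; |r| = 1 maps to p = 0.
* Degenerate inputs: zero-variance vectors → no significant
  correlation; constant Cox covariates → skipped with a warning;
  all-equal risk scores → everyone low-risk with a warning.
* Expression TSVs are written with `%.17g` and read with pandas'
  round-trip float parser, so write/read cycles are bit-exact.
* All tolerances asserted in the tests: 1e−12 for oracle equivalence of
  correlation blocks, BH adjustment and rank-based AUC; 1e−9 for
  entropy closed forms.

## Known limitations

* The DE screen is unpaired and unmoderated; small cohorts with strong
  mean–variance coupling would benefit from a moderated replacement.
* Knee selection reacts to the single largest drop; score curves with
  several comparable drops are better served by the fixed-Q override.
* The multivariate Cox reduction (joint fit → prune by Wald p → refit)
  is one of several defensible rules; stepwise and penalised selection
  are intentionally not implemented.
* The time-dependent ROC estimator is the unsmoothed KM construction;
  it can be non-monotone for heavily tied markers.
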