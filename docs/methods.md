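# Methods

## Problem setting

Pseudomyxoma peritonei (PMP) disseminates locoregionally in the
peritoneum, so one patient typically harbors many lesions, and a single
biopsy may not represent the disease. `pmprisk` classifies patients into
good/poor prognosis groups from bulk expression profiles by combining a
cancer-cell signal (the HRAC signature score) with a stromal signal (the
CAF signature score), reducing multifocal patients to a representative
lesion first. This note records the exact procedures, the modeling
choices made where the design was open, and what the synthetic
validation does and does not establish.

## Preprocessing

Raw probe intensities (linear space, strictly positive) pass through:

1. **Detection filter** — keep probes with a detectable signal
   (detection p-value = 0) in at least one sample. The exact-zero rule
   matches bead-array detection calls; platforms that never emit exact
   zeros can raise the cutoff via `max_detection_p`.
2. **Probe collapse** — one row per gene symbol, keeping the probe with
   the highest signal variance across samples. Variance is ranked in
   log2 space by default (`variance_space`), because variance ranking is
   not invariant to the transform and log2 is where bead-array spread is
   usually compared. Exact variance ties resolve to the
   lexicographically smallest probe id, making the result independent of
   row order. Symbols match case-insensitively after whitespace
   stripping; no alias resolution is attempted.
3. **Between-sample normalization** — cyclic loess by default (span 0.7,
   2 iterations), quantile as the alternative. The default *fast*
   variant fits one loess trend of M (log2 ratio) vs A (mean log2
   signal) per sample against the cohort mean profile per iteration;
   the full pairwise cycle (`variant="pairs"`) fits all sample pairs and
   scales quadratically in sample count. Both remove intensity-dependent
   per-sample biases; quantile normalization instead forces identical
   marginal distributions (sorted columns exactly equal). Input and
   output stay in linear space. All loaded samples — including CRC
   controls — are normalized jointly.

The matrix object carries an explicit `space` flag (`linear`/`log2`)
because the two scores are defined in different spaces, and every
operation validates the space it needs rather than converting silently.

## Scores and calls

* **Central sample** (two uses, one definition): the profile with
  maximal Pearson correlation, over all genes in log2 space, to the
  per-gene mean profile of a set — the whole cohort when choosing the
  HRAC log2-ratio reference, or one patient's lesions when choosing the
  representative lesion. Correlations are rounded to 12 decimals so
  mathematically exact ties (e.g. constant shifts) resolve
  deterministically by sample order; constant-expression samples are
  excluded with a warning (their correlation is undefined). Euclidean
  distance to the mean profile is available as an alternative
  closeness metric for the patient-level selection.
* **HRAC score**: mean log2 ratio of the signature genes versus the
  central reference; the reference scores exactly 0, and the score is
  invariant to any global rescaling of the linear matrix.
* **CAF score**: mean linear-space signal of the CAF signature genes.
  Because a raw linear mean is always positive while the call semantics
  need a signed score, the cohort-median raw score is subtracted by
  default (`centering="cohort_median"`); the centering constant is kept
  as provenance. The raw mean (`centering="none"`) is used for
  between-group comparisons such as PMP vs CRC.
* **Median-threshold call**: high iff score > cohort median (strict, so
  the median sample itself is low; even cohorts use the midpoint of the
  two central order statistics). The threshold cohort defaults to all
  scored PMP samples — CRC controls never enter thresholds or the
  central-reference choice.
* **Integrated call**: high iff HRAC-high OR CAF-high. The OR rule is
  monotone by construction and targets the simulated hazard structure
  (below) exactly.
* **Signature coverage**: scoring aborts when fewer than half of a
  signature's genes are present in the matrix (configurable
  `min_coverage`); partial coverage is logged.

## Multifocal patients

Per-patient reduction strategies: `central` (score of the representative
lesion), `mean_profile` (gene-wise average of the lesion profiles in
linear space, scored as a pseudo-sample against the same reference),
`mean_score`, `highest`, `middle` (median; midpoint for even lesion
counts), `lowest`. A patient is *discordant* when the lesion scores
contain both a strictly positive and a strictly negative value (exact
zeros count as neither).

In the headline path (`analysis_set="central_samples"`, the default) the
analysis set is rebuilt from one central sample per patient and the
cohort reference, CAF centering and median thresholds are **recomputed
on the reduced set**. The alternative (`all_samples`) thresholds per
patient on scores aggregated from the full sample set. Recomputation on
the analysis set in use keeps every run self-contained; external
single-lesion cohorts likewise recompute their own thresholds.

## Evaluation statistics

All implemented in-package (scipy supplies only distribution functions);
lifelines / scikit-learn / scipy.stats serve as independent cross-checks
in the tests.

* **24-month DFS binarization**: event at ≤ 24 months → positive;
  followed to ≥ 24 months → negative; censored before 24 months →
  indeterminate, excluded from ROC with a logged count (the standard
  horizon-censoring treatment). Events exactly at the horizon count as
  within it.
* **ROC/AUC**: empirical curve over all score thresholds, tied scores
  grouped, trapezoidal area — identical to the Mann–Whitney concordance
  with half credit for ties (property-tested against an O(n²) pair
  count).
* **DeLong**: AUC variance/covariance via placement values (midranks);
  paired z-test for two correlated AUCs; normal-approximation CI
  truncated to [0, 1]. A degenerate variance with equal AUCs returns
  z = 0, p = 1 (the self-comparison case); with unequal AUCs it returns
  a flagged result instead of dividing by zero.
* **Kaplan–Meier**: product-limit estimator on the grid of distinct
  observed times; censored units leave the risk set after their time.
* **Log-rank**: per distinct event time, hypergeometric expectation and
  variance of the per-group event count; two groups use the classic
  (ΣO−ΣE)²/ΣV statistic on 1 df, k groups the quadratic form with the
  covariance matrix on k−1 df (provided but not exercised by the
  headline path). No events at all → statistic 0, p 1, flagged.
* **Cox proportional hazards**: Newton–Raphson on the Breslow partial
  likelihood (adequate at these cohort sizes), convergence at gradient
  max-norm < 1e-8 or 100 iterations, with step halving. Constant
  covariates carry no information and are reported with coef 0 / HR 1.
  Rank-deficient designs are flagged, not fitted. Because a monotone
  likelihood (complete separation) lets the gradient vanish at huge
  coefficients, fits with |coef| > 30 or standard errors two orders of
  magnitude above the coefficient scale are flagged as non-converged.
* **Welch t-test** (pooled variant optional): two-sided; the degenerate
  zero-variance case returns p = 1 for equal means and a flagged p = 0
  otherwise.

## Synthetic cohort generator

The generator is first-class, tested code: it provides cohorts with
known latent structure so every pipeline stage has a ground truth.

Structure (defaults = the study conditions): 24 patients, 13/24 DPAM,
multi-lesion probability 9/24 with 2–4 lesions when multifocal, a
139-gene cancer-cell signature, a 50-gene stromal signature, 11 CRC
controls, 2000 genes total (desk scale; gene count does not affect the
score model beyond averaging noise).

Expression model, per lesion, in log2 space: gene baselines ~
N(7, 1); i.i.d. lesion noise N(0, 0.2) per gene; HRAC genes shifted by
+shift/2 (latent HRAC-high patients) or −shift/2 (latent-low), so the
two classes differ by exactly `hrac_log2_shift` (default 1.0) in mean
log2 ratio; CAF genes multiplied in linear space by
(0.25 + 1.5·caf_fraction), where the lesion's stromal fraction is Beta
distributed (concentration 40) around the patient's latent level — 0.7
for latent CAF-high, 0.3 for CAF-low, 0.15 for CRC controls (chosen once
as a realistic strong-stroma vs weak-stroma contrast; CRC controls also
carry the low HRAC level). Latent factors are independent Bernoulli(0.5)
at patient level. **Outlier lesions** (probability 0.1, multifocal
patients only) flip the sign of their patient's HRAC deviation,
reproducing intra-patient sign discordance; a flipped lesion in a
single-lesion patient would be unidentifiable, hence the restriction.

Survival: DFS ~ exponential with hazard 0.012/month ×5 per latent-high
factor (multiplicative, i.e. log-additive — so the OR-rule classifier
has a correctly specified target), independent exponential censoring
(0.004/month) and a 60-month administrative horizon; OS uses half the
DFS hazard. At these rates a latent-low patient relapses within 24
months with probability ≈ 0.25 and a doubly-high patient ≈ 0.999,
mimicking the indolent-vs-aggressive contrast of the disease. All draws
derive from one master seed (gene baselines are shared between the
cohort and its CRC controls so the matrices concatenate).

What the generator does **not** emulate: microarray noise physics (dye
or spatial artifacts), probe-level structure (it emits gene-level
matrices; probe filtering/collapse are tested on separate fixtures),
correlation between histology and the latent factors, gene–gene
correlation beyond the two signature blocks, and non-exponential
hazards. Passing recovery tests therefore demonstrates the pipeline's
correctness and the value of central-sample selection under the stated
model — not clinical performance on real cohorts.

## Recovery behavior and known limitations

* The median-threshold rule always calls exactly ⌊n/2⌋ of n distinct
  scores high, while the latent high-risk count fluctuates binomially;
  on a 40-patient strong-signal cohort this caps integrated-call
  accuracy at roughly 0.85–0.975 depending on the draw (mean ≈ 0.91).
  This is a property of the thresholding rule, not an implementation
  artifact.
* With outlier lesions enabled, the central-sample strategy discriminates
  24-month DFS at least as well on average as taking each patient's
  highest or lowest lesion score; with only two lesions the central
  choice between a normal and a flipped lesion is near-symmetric, so the
  advantage grows with lesion count.
* Pearson-based central-sample selection can favor a high-variance
  outlier lesion when the patient has very few lesions and the outlier's
  noise dominates the mean profile; the Euclidean metric option behaves
  differently in such corners.
* The headline published AUCs and log-rank statistics of the motivating
  study depend on its accession data and on externally published gene
  lists that are not redistributed here; this package reproduces the
  *method* and validates it on synthetic ground truth, and accepts
  user-supplied matrices and signature lists for real-data runs.
* Problem sizes in the test suite and acceptance script (desk-scale gene
  counts, 50-seed strategy comparison, 1000-replicate calibration) were
  chosen to keep a full run in the tens of seconds while leaving the
  Monte-Carlo error well inside the asserted margins.
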