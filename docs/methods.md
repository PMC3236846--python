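# Methods

This note documents the models, defaults and numerical choices behind
`gridvote`, and what the synthetic experiments can and cannot show.

## The modeling protocol

The package implements a fixed classifier-development protocol for
binary expression endpoints. Inputs are sample × feature matrices of
log2-scale summarized intensities (the package never re-logs or
normalizes), P/N class labels, and per-sample batch identifiers.

**Batch correction** is center mean shift: for feature *f* and batch
*b*, `x − mean(f, b) + mean(f)`. It equalizes within-batch feature means
across batches, leaves overall feature means unchanged, and is
idempotent. It is fit on training data only; a fitted corrector can
transform further samples from batches it has seen, and passes samples
from unseen batches through unchanged. External validation sets come
from their own batches, so they are effectively left uncorrected — a
deliberately conservative reading of blinding in which no validation
statistics influence any modeling step (labels would not be needed for
centering, but the strictly training-fit contract is simpler to audit).

**Class rebalancing** duplicates minority samples, drawn uniformly with
replacement, until the classes are even — but only when the
majority/minority ratio is *strictly* greater than 4 (direction-
agnostic). Duplicates get suffixed sample ids; originals are never
altered or dropped. Seeds derive from (run seed, endpoint, repeat,
fold), so the complete CV is reproducible.

**Feature ranking.** The FC+p method drops every feature with two-sided
pooled-variance Student t-test `p ≥ 0.05` and sorts survivors by
absolute fold change (difference of class means on the log2 scale — the
data are already logged, so no unlogging). The SAM method sorts all
features by the absolute relative difference
`d = (x̄_P − x̄_N) / (s_i + s0)` with
`s_i = s_p · sqrt(1/n_P + 1/n_N)` (pooled scatter) and the
exchangeability constant `s0` set to the median of `s_i` over features —
the simple, standard stabilizer; the original percentile optimization of
`s0` is intentionally out of scope. With `s0 = 0`, `|d|` ordering equals
`|t|` ordering (asserted by test). Ties break by smaller p then feature
id (FC+p) or feature id (SAM). Feature sets are nested prefixes of the
ranking: sizes 5, 10, …, 200 (40 sets), capped at the number of
survivors when fewer remain; a config whose method yields an empty
ranking in every fold is reported as skipped, never as MCC 0.

**Learners.** KNN uses Euclidean distance over the selected features and
majority vote among the k nearest; neighbors sort by (distance, training
sample id), which makes predictions deterministic even when oversampling
has duplicated rows, and odd k makes vote ties impossible. The K grid is
{1, 3, 5, 7, 9, 11, 13} — the protocol fixes only "7 values of K", so
the odd integers up to 13 are this package's documented choice. Gaussian
Naive Bayes stores per-class feature means, maximum-likelihood variances
floored at `1e−9 ×` the mean feature variance (guarding zero-variance
features created by duplicated rows), and training-frequency priors
(≈ uniform whenever rebalancing fired); prediction is the larger
`log prior + Σ log N(x; μ, σ²)`, ties to negative.

**Complete cross-validation** is stratified 5-fold CV repeated 10 times
(50 runs). The protocol fixes "5-fold" and "50 runs" but not the repeat
structure; 10 × 5 is the unique consistent rectangle. Stratification is
needed because minority fractions down to P/N 0.1 would otherwise yield
single-class folds. Every step above is redone inside each training
fold; the held-out fold is only transformed (batch centering with
fold-fit means) and scored. Per config the package averages MCC,
accuracy, sensitivity and specificity over the 50 folds (degenerate
confusion margins give MCC 0 by convention — all-one-class folds do
occur at small n) and pools the out-of-fold predictions into a training
positive-prediction rate. Fold assignments are derived from sample ids
in canonical order, so results are invariant to the row order of the
input (asserted by test).

**Nomination** walks a hierarchical decision tree: (1) keep the top
group of models after rounding CV MCC to one decimal, half away from
zero (0.89 and 0.91 share the 0.9 group; 0.85 rounds to 0.9); (2) keep
the smallest feature count, and among models within one grid step (≤ 5
features) of it — the quantification of "nearly the same number of
features" — prefer higher accuracy, then sensitivity, then specificity;
(3) prefer SAM; (4) prefer KNN; residual ties go to smaller K, then
config id. The full chain is deterministic and order-invariant.

**Calibrated-vote ensemble.** The top `ceil(fraction · n)` configs by
mean CV MCC are retained (default fraction 0.5; ties at the cut-point
are included rather than arbitrarily dropped), each refit on the fully
processed training set. Each retained model's training
positive-prediction rate is its pooled out-of-fold rate from complete
CV — not a refit-on-train prediction, which for KNN with k = 1 would
degenerately equal the training prevalence (each sample retrieves
itself); an honest rate is already available from CV. Their mean is p̄.
A sample is called positive iff (fraction of retained models voting
positive) / p̄ ≥ 1; with p̄ = 0.5 this is exactly majority vote with
ties positive. p̄ of 0 or 1 is a hard error pointing the user at the
controls. Raising the fraction never drops a retained model.

**Blinding** is structural: validation labels live only in the answer
key; the prediction path receives a label-free copy, and a test proves
that inverting the key flips the scores without changing a single
frozen prediction.

## The synthetic endpoint generator

Each endpoint draws samples from two Gaussian classes in feature space:
`n_informative` features gain a mean shift of `effect_size` in the
positive class, all features carry i.i.d. noise (`noise_sd`), and every
(batch, feature) pair adds a Gaussian offset (`batch_sd`), with batches
assigned round-robin after label assignment so batch is independent of
class. Class counts follow `n_pos = round(n · r / (1 + r))`, ties away
from zero — the rule that makes the printed P/N ratios exact. Validation
sets use the same feature model, their own P/N ratio and fresh batches.
One RNG stream per (suite seed, endpoint code) makes endpoints
independently reproducible.

Under this model the optimal error rate has the closed form
`Φ(−effect·√m / (2·noise_sd))` for `m` informative features. Defaults:
1000 features (200 in the reduced preset), 30 informative,
`effect_size` 1.0, `noise_sd` 1.0, 2 batches, `batch_sd` 0.5. Negative
controls have 0 informative features (labels independent of the matrix
by construction); positive controls use `effect_size` 3.0, far beyond
the < 1% Bayes-error requirement the spec of a positive control implies
— the generator refuses positive-control specs that are not separable.

The 13-endpoint default suite copies the benchmark sizes and P/N ratios
(e.g. endpoint D: 130 training samples at P/N 0.34, 100 validation at
0.18). The reduced preset keeps endpoints D (imbalanced real, no
oversampling), H (positive control), I (negative control) and J (real,
train P/N 0.10 — exercises the oversampling trigger), with 200 features,
feature sets up to 50, and 5 × 5 CV; these problem sizes are the
package's scale for routine experiments and let a full suite run in a
few seconds on one core.

**What the generator does not emulate:** microarray intensity
distributions, probe-level artifacts, gene–gene correlation,
heterogeneous effect sizes, or batch–class confounding. Consequences for
interpretation:

* Passing control-endpoint tests shows the pipeline is leak-free and can
  recover strong signal; it says nothing about weak-signal biology.
* With 30 independent informative features at effect 1.0 the real
  endpoints have a Bayes error of ≈ 0.3% — nearly as separable as the
  positive controls. In this regime cross-validated selection is well
  calibrated, the nominated model already sits high among all configs'
  validation MCCs, and the two deciders differ only marginally (the
  ensemble matches or beats nomination in a majority of instances, but
  its average percentile placement is not higher). The pronounced
  ensemble advantage reported on real consortium data arises from weak,
  heterogeneous signal and noisy CV estimates — conditions this
  homogeneous Gaussian generator deliberately does not create. The
  replication analysis (`analysis/04_replicate_comparison.py`) quantifies
  this regime difference.

## Numerical and degenerate-input conventions

* MCC is 0 whenever a margin of the confusion table is empty; empty
  tables are an error.
* Sensitivity/specificity are 0 on empty denominators.
* The paired endpoint t-test excludes the random-label (negative
  control) endpoints, and reports zero-variance differences as a
  degenerate flag instead of a p-value; two-sided by default, one-sided
  by flag.
* Percentile placement uses mid-rank (half credit for ties), so
  "above/below the median" statements are stable under ties.
* One-decimal MCC grouping rounds half away from zero, after an
  epsilon-rounding shield against binary float representation.
* Dataset export writes 6 decimal places; readers accept any parseable
  float, so write→read is exact at the declared precision.
* Grid evaluation computes each (fold, method) ranking once and reuses
  it across all feature-set sizes and learners, growing KNN distance
  matrices incrementally over the nested prefixes; a test asserts exact
  equivalence with naive per-config recomputation.

## Known limitations

* The SAM `s0` median rule and the K grid are documented stand-ins for
  unpublished details of the original protocol.
* Validation sets from unseen batches are not batch-corrected (see
  above); with `batch_sd` at its default this adds a modest domain shift
  that affects both deciders.
* The ensemble is an unweighted vote; weighted or stacked variants, SMOTE
  style oversampling, model-based batch correction and SAM FDR
  thresholding are out of scope.
* No parallel execution; determinism is prioritized over speed, though
  the full 8320-model grid on 13 endpoints remains practical on one
  core.
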