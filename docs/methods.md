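# Methods

## Problem and pipeline

Two patient groups — coeliac disease (CD) and diarrhoea-predominant IBS
(D-IBS) — are to be discriminated from the volatile-compound signal of
urine headspace. A FAIMS scan of one headspace draw is an ion-current
matrix over (dispersion field %, compensation voltage V), one matrix per
ion polarity, acquired in replicate. The analysis chain is:

1. **Aggregation.** Each patient's replicate scan pairs are flattened
   row-major (positive polarity first, then negative) and averaged
   element-wise. Averaging at patient level keeps every patient a single
   cross-validation unit, so replicates can never straddle folds.
2. **Wavelet compression.** The data vector is zero-padded to the next
   power of two and decomposed with a 1-D Daubechies wavelet
   (`pywt.wavedec`). Localized chemical peaks compress into few large
   coefficients, which is what makes the downstream sparse selection
   effective. The padding is deterministic and data-independent, so it
   carries no class information.
3. **Variance filter.** Coefficients whose unbiased sample variance across
   the *training* patients falls below a cutoff are removed as
   noise-dominated. The cutoff may be absolute or a quantile; the default
   keeps the top 5% of coefficients by variance.
4. **Rank-sum ranking.** Surviving coefficients are ranked by the two-sided
   Wilcoxon rank-sum p-value between classes (exact by enumeration for
   combined sample sizes ≤ 12 without ties, normal approximation with tie
   and continuity corrections otherwise); the `k = 30` smallest-p features
   are kept, ties broken toward the lower coefficient index.
5. **Classification.** Elastic-net logistic regression (default), random
   forest, or SVM, each behind the same fit/predict-probability contract,
   with features standardized on the training fold.
6. **Leave-one-out cross-validation.** Steps 3–5 are refit inside every
   fold on the n−1 training patients; step 1–2 are per-sample and safe to
   precompute. Each patient therefore receives one held-out probability of
   CD from a model that never saw them.

## Evaluation conventions

* AUC is the Mann–Whitney ranking probability (ties ½), identically the
  trapezoidal area under the empirical ROC staircase.
* The operating threshold maximizes Youden's J; ties go to the smaller
  threshold. The calling rule is `prob_cd ≥ threshold → CD`.
* Sensitivity/specificity intervals are exact Clopper–Pearson (Beta
  quantiles): guaranteed ≥ nominal coverage, closed-form at the boundaries
  (lower bound 0 at 0 successes, upper bound 1 at all successes, lower
  bound `0.025^(1/n)` at n/n for 95%).
* The AUC interval is a class-stratified percentile bootstrap (2000
  resamples, seeded). Stratification resamples cases and controls
  separately, so every resample contains both classes and no degenerate
  redraw path is needed. Coverage is verified by simulation against the
  binormal closed form AUC = Φ(μ/√2).
* Report tables: probability bins 0–0.2 … 0.8–1 (upper bin right-closed)
  against Marsh grade for CD patients; per-group box-and-whisker numbers
  with whiskers truncated at twice the interquartile range beyond the
  quartiles; a samples × selected-features heatmap matrix. The heatmap's
  selection is refit on the full cohort — it is a descriptive display, not
  part of the cross-validated evaluation.

## Synthetic cohorts

The generator reproduces the study design: 27 CD vs 20 D-IBS patients,
three replicate scan pairs each, 51 × 512 grid per polarity (tests and
calibration studies use a reduced 16 × 64 grid purely to make hundreds of
full LOO-CV runs cheap; the structure scales with the grid).

A scan is a smooth background ridge plus 2-D Gaussian blobs at fixed
fractional grid positions:

* 4 *shared* blobs: amplitude `base_amplitude (4.0) + N(0, patient_sd)` per
  patient — common metabolites with biological variability;
* 3 *discriminative* blobs: the CD mean amplitude exceeds the D-IBS mean by
  `effect_size` × pooled between-patient SD (Cohen's d scale; default
  d = 2);
* between-patient SD defaults: 1.0 (CD) and 2.0 (D-IBS) — the D-IBS class
  is deliberately the noisier one, reflecting the large patient-to-patient
  variation expected in IBS;
* replicates share the patient's latent amplitudes and differ by i.i.d.
  pixel noise (`noise_sd = 0.5`, chosen so that replicate noise is clearly
  smaller than biological variation, as replicate instrument scans of one
  sample should be).

Randomness comes from one seed split per patient by counter
(`default_rng([seed, patient_index])`), so cohorts are reproducible
independently of generation order. `permute_labels` shuffles only the
labels and is the null-hypothesis generator.

Chromatograms are Gaussian peaks (σ = 0.02 min) on a flat 0.3 MCps baseline
with 0.05 MCps noise: four common peaks at 5.30, 7.63, 7.95 and 9.76 min in
both classes, two sub-threshold bumps (≤ 1.5 MCps) in both, and a CD-only
marker at 4.67 min (≈ 2.6 MCps). Retention jitter is clipped at 0.04 min,
inside the 0.05 min binning tolerance.

What the generator does **not** emulate: real FAIMS peak geometry and
inter-peak chemistry, drift/humidity effects, heavy-tailed or correlated
instrument noise, class overlap in peak *positions* rather than amplitudes.
Passing tests therefore validate the statistical machinery — calibration,
nesting, recovery, interval construction — not clinical performance on real
urine data, which would require the undeposited cohort.

## GC-MS screen

Peak detection subtracts a rolling-median baseline (0.5 min window, wide
enough to ride under sharp peaks while tracking drift), then takes local
maxima strictly above the 1.8 MCps floor with a prominence of at least half
the floor (suppresses noise wiggles on peak flanks). Bounds are at 90%
height drop. Binning is greedy in retention-time order: a peak joins the
current bin while within 0.05 min of the running bin center and 0.10 min of
the bin's first member, which partitions the peaks into bins of span
≤ 0.10 min — merging run-to-run jitter without merging the reported
compounds at 7.63 and 7.95 min. A bin is class-unique when ≥ 90% of one
class's samples contribute a peak and the other class contributes none
(strict absence).

## Numerical and design notes

* Wavelet default db4; order is configurable (the method fixes only the
  Daubechies family). Periodic (periodization) boundary is the default —
  orthonormal on power-of-two lengths, hence energy-conserving; zero-pad
  extension is available.
* The rank-sum statistic and p-values come from `scipy.stats.mannwhitneyu`
  behind the pipeline's branch rule; tests hold an independent brute-force
  enumeration oracle against it.
* Elastic-net defaults: mixing 0.5, fixed C = 1 on ≤ 30 standardized
  preselected features. A per-fold 5-fold internal CV over a C grid is
  available (`c_grid` hyperparameter) and, when used, runs inside the outer
  training fold; it is off by default because a fixed moderate penalty is
  standard at this feature count and keeps large calibration studies (which
  run ~10⁴ classifier fits) cheap without touching the nesting guarantees.
* sklearn's saga stopping rule watches only the penalized coefficients, so
  when a strong l1 penalty zeroes them all the solver can halt with the
  unpenalized intercept unconverged. In that regime the optimum is
  closed-form — intercept = logit(training prevalence) — and the fit
  applies it directly, restoring the intercept-only contract
  (probability ≈ prevalence under extreme penalty).
* SVM scores are the signed decision margin; the probability contract maps
  them through a logistic link, which is monotone and therefore
  ROC-equivalent to the raw margin.
* Determinism: every stochastic component (generator, bootstrap,
  classifiers) is seeded; ties everywhere break by ascending index.

## Calibration results and a known limitation

With no planted effect (d = 0), the nested harness averages held-out AUC
≈ 0.50 over 100 synthetic cohorts — the LOO-CV estimate is unbiased under
the null even though every fold actively selects features. A deliberately
leaky variant that fits the selection on all patients before the CV loop
inflates the null mean to ≈ 0.57–0.58 under the default generator, and to
≈ 0.78 when the candidate coefficients are independent noise
(`patient_sd = 0`). The gap has a clean explanation: the default
generator's between-patient blob variance concentrates the top-variance
mask on a few correlated latent amplitude factors, so the effective number
of independent candidates for spurious selection is small and the selection
bias saturates well below what uncorrelated candidates produce. Selection
leakage is therefore most dangerous exactly when the candidate features are
many and independent — worth remembering when the variance filter is loose
or the grid is large.
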