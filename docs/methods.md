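# Methods

`connmvpa` implements a whole-brain resting-state functional-connectivity
discrimination analysis for a two-group (patient/control) cohort, together
with a synthetic-cohort generator so the entire pipeline can be exercised
and validated without scan data.

## Pipeline model

Each subject contributes a T × R matrix of regional mean BOLD time series
(R = 90 regions by default, T ≈ 175 usable timepoints at TR = 2 s). The
analysis proceeds:

1. **Preprocessing.** Per region: linear detrend (least-squares line
   removal), ideal band-pass 0.01 Hz < f < 0.08 Hz, then OLS nuisance
   regression against any supplied confound columns (an intercept is
   always included, so the no-confound case is mean removal). Each stage
   is a linear projection and therefore idempotent.
2. **Edge features.** Pearson correlation between every region pair,
   Fisher z-transform (arctanh, correlations clipped at 1 − 1e−7 to avoid
   infinities), and row-major strictly-upper-triangle vectorization:
   D = R(R−1)/2 features, 4005 for R = 90. The 0-based edge ordering is
   fixed package-wide so feature indices are comparable across folds and
   files.
3. **Feature ranking.** Per feature, the cross-group Kendall tau over all
   m × n patient–control sample pairs (within-group pairs are not
   counted): τ = (n_c − n_d)/(m·n), where a pair is concordant when the
   feature difference has the same sign as the label difference. Tied
   feature values count in the denominator but as neither concordant nor
   discordant. With labels −1 = patient, +1 = control, τ > 0 means the
   connectivity is lower in patients. Features are ordered by |τ|
   descending; ties break toward the smaller edge index so that consensus
   sets are reproducible. (For binary labels this τ is affinely related
   to the Mann–Whitney U count, which the test suite uses as an
   independent oracle.)
4. **Classifier.** The top-k features are centered on the training mean
   and projected onto the top-d eigenvectors of the training covariance
   (sample covariance, 1/(n−1)); a soft-margin linear SVM with cost C is
   trained on the reduced coordinates. The decision score is
   Y = wᵀUᵀ(x − x̄) − b; Y > 0 predicts control, otherwise patient
   (exact zero goes to the patient side, a deterministic boundary rule).
5. **Leave-one-out cross-validation.** Each subject is held out once;
   ranking, selection, PCA and SVM are all refit on the remaining N − 1
   subjects, so feature selection never sees the test subject.
   Performance is summarized as GR = (TP+TN)/N (accuracy),
   SS = TP/(TP+FN) (sensitivity, patients), SC = TN/(TN+FP) (specificity,
   controls); undefined denominators are reported as missing rather than
   zero. Consensus features are those selected in every fold; union
   features in at least one fold.
6. **Permutation test.** The full label vector is permuted n_perm times;
   each permutation re-runs the entire LOOCV including per-fold feature
   selection, and p = (1 + #{GR* ≥ GR₀})/(n_perm + 1). The add-one
   smoothing keeps p ≥ 1/(n_perm + 1) at finite n_perm. The published
   description of the permutation scheme is ambiguous about whether
   labels are re-permuted inside each fold; permuting the whole vector
   once per replicate gives one well-defined GR* per permutation and is
   the documented choice here.
7. **Reconstruction.** Because the fitted classifier is linear end to
   end, Y = (Uw)ᵀ(x − x̄) − b, so Λ = Uw assigns each selected feature a
   signed weight. Per-fold Λ vectors are embedded into the full D-length
   edge space (zeros at unselected features) before averaging — fold
   selections differ, and averaging must happen in a common space — and
   |Λ| is averaged over all N folds. Each edge's averaged weight is split
   half-and-half between its two incident regions, so the region weights
   exactly conserve the total feature weight (Σ regions = Σ Λ̄, the
   module's central algebraic check). The edge report recomputes τ on all
   subjects (a single value per edge, matching how such tables are
   published) and labels an edge "decreased" when τ > 0.

## Key parameters

| parameter | meaning | default | note |
|---|---|---|---|
| k | features kept per fold | 550 | sweep grid 50..800 step 50 |
| d | PCA components | 6 | grid 2..20; capped at min(k, n_train − 1) |
| C | SVM cost | 0.255 | grid 0.005 + 0.05·j, j = 0..39 |
| f_low, f_high | band edges (Hz) | 0.01, 0.08 | open interval; DC and boundary bins zeroed |
| n_perm | permutations | 100–1000 | p resolution is 1/(n_perm + 1) |

Hyperparameter selection via `grid_select` is non-nested by default (the
best LOOCV operating point is reported directly, with deterministic tie
breaking toward smaller k, then d, then C); this reproduces the common
small-sample practice, and the statistically cleaner nested variant can
be built from the same primitives by sweeping inside each training set.

Numerical choices: the band-pass is an ideal rectangular DFT mask rather
than an IIR filter, matching the convention of the resting-state
toolchains this pipeline models; the SVM uses libsvm's exact convex
solver with a tightened stopping tolerance (1e−8) so refits are
bit-reproducible and label-flip antisymmetric; PCA component signs are
fixed so each component's largest-magnitude entry is positive, making
Λ = Uw reproducible across runs.

## Synthetic cohorts

`synth.simulate_cohort` draws each subject's series from a zero-mean
multivariate normal: controls from a base covariance, patients from the
base with a set of planted edge correlations shifted by Δr. The base is
a 5-factor loading structure blended with the identity
(`base_density`·C + (1 − density)·I), giving block-like background
correlation reminiscent of resting-state networks; the planted matrix is
symmetrized, eigenvalue-floored at 1e−6 and rescaled to unit diagonal, a
deterministic repair with bounded perturbation of non-planted entries.
Per-subject linear drift (uniform slope within ±`drift_amplitude`) and
white noise (`noise_sd`) are added so the detrend and filtering stages
have real work to do. Defaults — 22 + 22 subjects, 90 regions, T = 175,
TR = 2 s, `base_density` 0.3, `noise_sd` 0.2, `drift_amplitude` 0.5 —
mirror the cohort structure of the small case-control studies this
pipeline targets; no published effect sizes exist for the altered edges,
so planted Δr values are free parameters of each experiment, not claims
about any real cohort.

What the generator does **not** emulate: hemodynamic response and
temporal autocorrelation (samples are white in time, so the nominal T
overstates the effective degrees of freedom less than real BOLD data
would), head motion, physiological noise structure, site/scanner
effects, and spatial maps of any kind. Passing recovery tests therefore
shows the estimator chain is correct and well-calibrated under the
stated sampling model — not that comparable accuracy would be reached on
real scans.

## Validation sizes

The test suite and `scripts/acceptance.py` run: parameter recovery on
44-subject, 90-region cohorts with 30 planted edges at |Δr| = 0.5
(LOOCV accuracy, top-|τ| recovery of planted edges, and 20 seeded
replicates of the dominant-region check, where 12 of the 30 edges share
one region); and permutation calibration on 20 replicate null cohorts of
8 + 8 subjects × 20 regions with 100 permutations each — a size at which
2,020 full LOOCV runs complete in about a minute while still giving the
uniformity check 20 independent p-values. Both sizes are the package's
validation choices and are stated here so they can be scaled up.

## Known limitations

- Non-nested hyperparameter selection optimistically biases the reported
  best GR; treat sweep maxima as model exploration, not unbiased
  accuracy estimates (the permutation test, which re-runs everything per
  permutation, is the honest significance measure).
- Summary-statistics helpers (`cohort_stats`) recompute two-sample t
  values from printed mean ± SD rows; published tables are themselves
  rounded, so recomputed t values can differ from printed ones in the
  second decimal (observed for one demographic row and two
  neuropsychological rows of the motivating study's table).
- The pipeline starts at regional mean time series; image-space
  preprocessing (realignment, normalization, smoothing, parcellation) is
  out of scope by design.
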