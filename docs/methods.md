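# Methods

This note documents the models, conventions and numerical choices behind
`physiocca`, and what the synthetic-data experiments do and do not show.

## Physiological preprocessing

Respiratory traces are cleaned in a fixed order: z-score → linear
detrend → replacement of samples deviating more than 3 scaled MAD
(1.4826 × MAD, the Gaussian-consistent estimate) from the moving median
in a centered 0.3 s window (120 samples at 400 Hz) by linear
interpolation → zero-phase (forward–backward) order-2 Butterworth
low-pass at 5 Hz → z-score.  Cardiac traces are z-scored and band-passed
0.3–10 Hz with the same filter family.  Zero-phase filtering is a
deliberate choice: causal filtering would introduce a frequency-dependent
phase delay that directly biases the lag estimates downstream.

*Idempotence.*  Cleaning an already-cleaned trace reproduces it only up
to ~1e-5, not machine precision: the moving-median outlier rule can
re-flag samples at smooth extrema (where the local MAD collapses), and
the final z-score couples filter edge transients into the interior
scale.  This is inherent to any thresholded outlier-replacement stage;
the property test asserts stability at 1e-4 on the interior 90 %.

**RVT** is the difference between the upper and lower envelopes of the
cleaned trace: peaks and troughs detected with a 1 s minimum separation
(breathing is slower than 1 Hz), linearly interpolated, with edges
clamped to the nearest extremum and the difference floored at zero.
**ENV** is the sliding-window maximum of the rectified trace (default
10 s; a Hilbert-magnitude variant is available via `env_mode`), **RV**
the sliding-window SD (default 6 s); windows shrink at the boundaries
rather than padding.  **HR** uses peak detection with a 0.3 s minimum
inter-beat interval; instantaneous HR = 60/IBI is assigned to interval
midpoints, outlier-replaced in the beat domain (3 scaled MAD against the
local 30 s median, plus a 30–180 bpm physiological gate) and
interpolated to the sample grid.  All measures are block-averaged within
each TR window to reach the frame grid (1200 frames at TR 0.72 s
consume exactly 345,600 samples at 400 Hz).

## Topographies and lag estimation

The global signal is the unweighted ROI mean per frame.  All frame
series are truncated by 10 frames at each end before correlation.  The
group lag maximizes the absolute group-averaged cross-correlation
between GS and a physiological measure on an integer frame grid over
±72 s, averaging Pearson r across runs within participant and then
across participants; ties break toward the smaller |lag|.  "Shifted
backward by L" pairs the physiological sample at t − L with BOLD at t;
correlations at lag are computed on the overlapping segment only, since
zero-padding would bias the profile toward small lags.  A negative peak
sets `flip`, and the flipped measure is used for the coupling map so
that (e.g.) RVTCORR and GSCORR live on comparable sign conventions.
Coupling values are Fisher z = atanh(r) with |r| clipped at 1 − 1e-7
(an exact ±1 correlation would otherwise produce an infinite z and
poison run averaging); per-run vectors are averaged across runs.

## ICC consistency maps

For each ROI, the two topographies across n participants form an n × 2
table decomposed by two-way ANOVA into row (participant), column
(measure) and residual mean squares.  The default variant is the
printed ratio σ²_r/(σ²_r + σ²_e) with σ²_r = MSR − MSE and σ²_e = MSE,
which equals (MSR − MSE)/MSR and omits the divisor by the number of
measures carried by the standard two-way forms; Shrout–Fleiss ICC(C,1)
and ICC(A,1) are selectable alternatives (cross-checked against
`pingouin`).  The reported variance component σ²_r is floored at zero,
but the ICC value itself is left on its algebraic scale — it can dip
below zero for discordant measures — so that its null expectation is
exactly zero rather than positively biased.  Network comparisons apply
the Kruskal–Wallis test to Fisher-z ICC grouped by atlas network,
excluding networks with fewer than 2 ROIs.

## Behavior preparation

Screening drops measures with a gross high outlier (more than 100 SDs
above the median), under 50 % valid entries, or a modal value covering
more than 95 % of the non-missing entries, then removes listed confound
and drop variables.  For the outlier rule the SD is estimated with the
extreme point excluded: if the point is included, the deviation is
algebraically bounded by √n (≈ 33 at a 1,100-participant cohort), and a
100-SD rule could never fire; leaving it out restores the rule's
intended ability to catch mistyped values.  A symmetric (two-sided)
variant is available behind a flag.

Each variable is z-scored on its non-missing entries and residualized
against an intercept-augmented confound matrix fitted on those entries;
missing cells stay missing.  Because columns are then mean-zero, the
participants × participants covariance is computed about zero from
pairwise-complete observations — with complete data it coincides with
the Gram matrix whose eigenvectors give PCA scores, which pins down the
estimator and makes the complete-data behavior exactly testable.  The
matrix is projected to the nearest symmetric PSD matrix by eigenvalue
clipping at 1e-10 × the largest eigenvalue (for symmetric input this is
the fixed point of the alternating symmetric/PSD projection), and the
top-k eigenvectors scaled by √eigenvalue are the behavioral component
scores.  Topography blocks are complete, so they use a plain SVD after
standardization and deconfounding.  Out-of-sample projection regresses
the (zero-imputed, standardized, deconfounded) training block onto the
training scores to obtain a variable-space basis; duplicated rows
project exactly onto their in-sample scores.

## CCA and permutation inference

The canonical decomposition is the classical QR + SVD construction:
center both blocks, thin-QR each, SVD the cross-product of the
orthonormal factors; singular values are the canonical correlations and
back-substitution through the triangular factors recovers the weights.
A rank check (10⁻¹⁰ relative tolerance on the R diagonal) rejects
degenerate blocks with advice to lower k.

Permutations respect family structure by shuffling whole families among
families of identical size with within-family order fixed; singleton
families therefore reduce the scheme to unrestricted permutation, and a
cohort with no two same-size families falls back to unrestricted
shuffling with a loud warning.  Row permutation commutes with the QR
factorization (P(QR) = (PQ)R), so each permutation costs one small
cross-product and one k × k SVD.  Mode m's p-value compares its
observed correlation against the null distribution of *first* (maximal)
canonical correlations, with an add-one correction
(1 + #{null ≥ r})/(1 + n_perm) that keeps p-values off zero.

Back-projection correlates a mode's participant scores with each
original variable; FWER control uses the max-|r| permutation null under
the same family blocks (significance when |r| exceeds the 1 − α null-max
quantile, α = 0.001 by default).  Observed weights use pairwise-complete
data; the permutation null uses the zero-imputed standardized block,
which at < 1 % missingness changes the null max negligibly.  Sign
alignment is anchored: if a named anchor variable's back-projected
weight does not carry the desired sign, all weights and scores of the
mode are negated jointly (an involution; the canonical correlation is
untouched).

Time-domain controls: `regress_out_series` residualizes a frame series
on lagged/flipped regressors over the frames where all regressors are
defined (returning the alignment slice), covering both the 0-lag
multi-regressor form applied to every ROI and the lagged single-regressor
form applied to GS or RVT; `regress_out_map` residualizes one
topography set on another per participant.

## Cross-validation

Folds are built by greedily assigning whole families to the currently
smallest fold (deterministic given the seed).  This is stronger than
keeping only MZ twins together — all family members share a fold — which
errs on the conservative side for exchangeability.  Per fold, component
reductions and the CCA are fitted on training rows only; test rows pass
through the training standardization, deconfounding, bases and weights,
and the out-of-sample r is the Pearson correlation of the mode-1 test
score pair.  Weight stability is the mean pairwise correlation across
folds of *full-length* training weights (correlations of training
scores with the original variables) — component-space weights are not
comparable across folds because each fold learns its own basis — with
each fold sign-aligned to the first.  Permutation significance re-pairs
the blocks within each fold's training set (family-blocked) and refits
the canonical weights; the per-block component reductions are
unsupervised and row-order invariant, so they need no refit, which keeps
the permutation loop cheap.  The per-fold decision rule is Bonferroni
style (significant if any fold p < 0.005); the mean-level p is reported
separately.

## Synthetic cohorts

The generator plants a recoverable answer for every stage:

- **Global component** g(t): AR(1) (φ = 0.9) innovations band-limited
  below 0.1 Hz and z-scored — resting-state-like spectral content
  without modeling hemodynamics.
- **Respiration**: an infra-slow modulator (band-limited noise,
  0.01–0.05 Hz, centered on the ~0.03 Hz range where end-tidal CO₂
  fluctuates) defines RVT on the frame grid; the belt trace is a 0.3 Hz
  carrier whose amplitude envelope follows the modulator, plus white
  noise.  BOLD receives the *negated* modulator delayed by
  `true_lag_frames` (default 16 frames = 11.52 s at TR 0.72 s) through a
  per-participant spatial map, exercising the pipeline's flip and lag
  conventions.
- **Cardiac**: a pulse train whose beat-to-beat rate follows an AR(1)
  heart-rate-variability process (white per-beat rates would trip the
  3-MAD beat-domain outlier rule, which real, autocorrelated HRV does
  not); its slow component couples weakly into BOLD at a +1 frame lag.
- **Spatial structure**: base global loadings Uniform(0.3, 1.0) per ROI;
  per participant, the loadings are tilted along a fixed unit direction
  by a brain latent z_p and jittered with map noise (SD 0.2).  With
  `coupled_maps` the respiratory map is 0.3 × the participant's
  loadings (high GSCORR–RVTCORR ICC by construction); otherwise an
  independent map (ICC near zero).  BOLD noise SD 1.0 puts GSCORR
  roughly in 0.3–0.9 Fisher-z and RVTCORR roughly in 0.05–0.2,
  i.e. the respiratory topography is markedly weaker than the GS
  topography, as in real recordings.
- **Behavior**: 60 measures loading on a behavior latent u_p with
  loadings Uniform(0.3, 0.7) and random signs, unit residual variance, a
  weak contribution from two confound covariates, and missing cells at
  0.93 %.  corr(z, u) = `true_canonical_r` (default 0.7).
- **Families**: 30 % of participants in MZ pairs, 20 % in DZ pairs, the
  rest singletons; both latents carry a family-level random effect
  explaining 30 % of their variance (a free parameter — the within-family
  behavioral correlation of twin cohorts is not pinned down here — chosen
  so family-blocked permutation is consequential).  All randomness flows
  through one seeded generator; identical seed and configuration are
  bit-identical.

What the synthetic cohorts do *not* emulate: hemodynamic response
shapes, motion and scanner artifacts, non-Gaussian behavioral
distributions, heritability structure beyond a shared family effect, and
breathing-rate variability (the belt carrier is fixed at 0.3 Hz).
Passing tests therefore demonstrate the correctness and calibration of
the estimators under the stated generative model, not performance on any
real cohort.

## Problem sizes and runtime

The test suite and acceptance script scale the experiments to desk
size: lag recovery uses 30 participants × 100 ROIs × 1200 frames with
full 400 Hz traces; permutation calibration runs 1000 null simulations
of 500 permutations each at n = 120 with k = 5 components (exact
blocked permutation keeps the type-I rate at its nominal 5 %); planted
mode recovery uses n = 500 with k = 20 components; the regression
control runs 50 paired simulations at n = 16 × 40 ROIs; the acceptance
script's main cohort is n = 300 × 100 ROIs × 800 frames.  The whole
suite completes in well under two minutes on one CPU.

## Known limitations

- The ENV definition ("envelope over a window") is ambiguous in the
  literature; the default is the windowed maximum of the rectified
  trace, with a Hilbert variant behind a flag.
- The pairwise-complete covariance is computed about zero; for columns
  that are z-scored this is the natural estimator, but it is not the
  row-centered covariance some toolboxes produce.
- The permutation null for back-projection zero-imputes sparsely
  missing cells; at the 0.93 % missingness modeled here the effect on
  the null-max quantile is negligible, but the approximation would
  degrade under heavy missingness.
- CV permutation significance permutes at the component-score level
  (valid because the reductions are unsupervised); refitting the
  reductions per permutation would be statistically equivalent under
  the null but orders of magnitude slower.
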