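# Methods notes

This note records the models behind `lamfmri`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
design decisions taken where the analysis conventions left room.

## Experiment model

The design is a 3 (stimulus modality: A, V, AV) × 2 (attended modality)
block experiment.  Defaults: 33 s activation blocks of 50 looming stimuli
at a fixed 660 ms onset asynchrony, preceded by 16 s fixation with an
attention cue 3 s before block onset; 18 blocks per run (3 per
condition), 4 runs over 2 days, a 20 s closing fixation; 302 volumes per
run at TR 3 s.  Weak targets (both modalities in every block) enforce the
attention manipulation: per condition, two thirds of blocks carry one
target per modality and one third carry two, i.e. 16 per modality per
condition.

Decisions where the convention is under-specified:

* **Looming sound amplitude.** The printed growth law is typeset
  ambiguously; we read it as `A(t) = A0·exp(0.68·t) − 1` with `t` in
  seconds.  The alternative grouping `A0·exp(0.68·t − 1)` differs only by
  a constant factor `e^-1` and an offset; neither changes any downstream
  analysis, which never consumes stimulus amplitudes.
* **Annulus lifetime.** An annulus is removed when it reaches the maximum
  radius (trajectory defined on `[0, (r_max − r_0)/v]`), rather than
  lingering at full size.
* **Block order** is a seeded random permutation constrained to 3
  occurrences per condition per run; no further balancing is imposed.
* **Target placement.** "Biased toward the end of the block" is realised
  as uniform sampling from the final half of the block; a ≥ 1 s
  separation between targets keeps response windows non-degenerate.
* **Units.** Seconds internally; milliseconds only at the API surface
  where the constants are conventionally printed in ms.

Behavioural scoring: a press answers target *k* iff it falls in
`[onset_k, min(onset_k + 2.5 s, onset_{k+1}))`; the windows are disjoint,
so hits and extra-responses partition the presses exactly.

## Synthetic data: what it emulates

`lamfmri.synth` generates, per subject, a `(vertices × 6 depths × 72
betas)` array over four flat 2D ROI patches (A1, PT, V1, V2/3), plus
voxel time series for the first-level model.  The planted structure:

* **Superficial bias**: a depth gain `g(f) = 1 + f` (f = equivolume depth
  fraction) multiplies all signals, emulating the roughly linear rise of
  gradient-echo BOLD toward the CSF boundary.
* **Crossmodal deactivation** for the non-preferred unisensory stimulus:
  laminar shape `C* + L*·x` with patchy vertex variation (smoothed
  Gaussian random fields).  Defaults: auditory ROIs (C*, L*) = (−1, 0)
  (constant deactivation); visual ROIs (−1, −0.3) (magnitude growing
  toward the surface).
* **Crossmodal modulation** in AV blocks (auditory ROIs only): a
  sign-varying patchy field, sd 0.5 (constant) and 0.2 (linear, per depth
  step), correlated ρ* = 0.8 with the deactivation fields — this is what
  makes unisensory deactivation topography predict audiovisual modulation
  topography, and what the decoder detects when the mean [AV−A] response
  is ≈ 0.
* **Attention**: a multiplicative, pattern-preserving gain
  `1 + 0.3·f` applied when the preferred modality is attended — the
  attentional contrast therefore grows toward the surface, and attention
  pairs stay more pattern-similar than stimulus pairs.
* **Noise**: i.i.d. Gaussian per beta (sd 0.5), run and day offsets (sd
  0.1 each), and Gaussian subject random effects on (C*, L*) (sd 0.2 and
  0.1) to exercise the group model.  Voxel time series add AR(1) noise
  and cosine drift to the HRF-convolved design prediction.

Study conditions are 11 subjects (the group-size regime the inference is
designed for) with desk-scale ROI sizes of 300/200/300/200 vertices; the
tests and the acceptance script use smaller patches (25–120 vertices,
3–6 subjects) where exact or qualitative checks do not need more — these
problem sizes are the package's own choice of desk scale.

What the generator does **not** emulate: draining-vein biophysics and
depth-dependent vascular point-spread beyond the monotone gain, 3D volume
/ k-space artefacts, registration error, mesh topology (patches are flat
grids because every in-scope statistic consumes per-vertex scalars), and
realistic across-depth noise correlations.  Passing tests therefore
validate the *estimators* — recovery, calibration, bias-removal — not the
physiological realism of any particular profile.

## First-level GLM

Canonical double-gamma HRF and its temporal derivative (nilearn's SPM
parameterisation: 6 s peak, 16 s undershoot) convolve the 18 block
boxcars and the target/extra-response events of each run; drift is a
DCT-II basis with `floor(2·T/128 s)` columns (14 at 906 s) plus constant.
Estimation is two-pass "global approximate AR(1)" GLS: OLS, pooled
(median-across-voxels) residual lag-1 autocorrelation, prewhitening of
both sides (first row scaled by √(1−ρ²)), OLS on the whitened system.
Pooling is per run; whether the original convention pooled per run or per
session is not stated, so the choice is documented rather than guessed.

A property worth knowing: with the full 56-column run design, the drift
and block columns absorb most of the slow noise, so the pooled residual
ρ̂ is biased toward zero — GLS betas remain unbiased (prewhitening only
trades efficiency).  The estimator's consistency is demonstrated at 1200
samples with a small design, where ρ̂ recovers the planted value within
±0.05.

All-zero event columns (no targets scheduled, no extra responses) are
flagged degenerate and excluded from estimation rather than breaking the
rank check.  Only the activation-block HRF betas are retained downstream:
18 × 4 runs = 72 per subject.

## Laminar machinery

* **Equivolume depths** use the per-vertex 1D closed form: with
  cross-sectional area interpolating linearly between the WM and pial
  area proxies, the k-th of n surfaces sits at the depth enclosing the
  fraction (k−½)/n of column volume (quadratic formula; equidistant in
  the equal-area limit).  The full 3D level-set construction is out of
  scope.
* **Depth convention**: index 0 = deepest (WM), 5 = most superficial
  (CSF), everywhere.
* **Sampling** along surface normals is trilinear; out-of-volume samples
  are NaN and the vertex is excluded from every analysis (a vertex must
  have all six depths; no imputation).
* **ROI profiles** take the median over vertices per depth (the
  per-vertex estimate distribution is heavily skewed superficially).
* **Shape GLM**: regressors `1` and centred `x = (−2.5 … +2.5)` are
  exactly orthogonal, so C is the mean and L the closed-form OLS slope.
  The per-depth-step unit of L is a package convention — only the shape is
  fixed by the analysis — so absolute L values are comparable within, not
  across, conventions.  No quadratic term is included; U-shaped profiles
  are not modelled.

## Group step-down

The 2 (shape) × 2 (ROI) table with a random subject intercept is tested
in a gated sequence (each stage requires the previous one significant at
α = 0.05): joint F on the ROI-averaged (C, L); per-shape tests; per-ROI
t-tests.  One-sided alternatives (negative constants) apply to the
crossmodal-deactivation contrasts at stages 2–3, reflecting the a-priori
direction of those effects.

Because the design is balanced with (by default) one value per
subject-cell — subject-level shape estimates are averaged over the 12
blockwise estimates first; blockwise entry is available behind a flag —
the mixed-model tests reduce exactly: stage 1 is Hotelling's T² on the
per-subject (C, L) ROI averages (F(2, n−2)); stages 2–3 are one-sample
t-tests (df n−1).  We use these reductions rather than plug-in Wald
F-statistics with residual degrees of freedom (F(2, 4n−4)-style): the
plug-in form treats estimated variance components as known and is
anti-conservative at n = 11, whereas the reductions give exact type-I
control under the model — which the test suite verifies by simulation.
A consequence is that printed degrees of freedom follow the reduction
(e.g. F(2, 9) at n = 11), not the residual-df convention.  The
statsmodels MixedLM fit is retained for cell means and variance
components and is cross-checked against the balanced closed form.

## MVPA

Per depth: linear SVC, cost 1 (sklearn's libsvm backend), leave-one-run-
out; features are mean-centred within the training set and, separately,
within the test set (no statistic of the held-out run touches training —
asserted by an artifact-injection test).  Decision ties go to the class
with the lower label index, deterministically.  Pooled comparisons stack
blockwise samples (24 vs 24), they do not average attention conditions.
Accuracy profiles are chance-corrected (−0.5) before the shape GLM, so C
tests above-chance decoding and L a depth trend; accuracy being bounded
in [0, 1] makes these profiles compressive near ceiling, which is why the
end-to-end checks read them qualitatively.

Pattern similarity uses condition-mean patterns averaged across blocks,
runs and depths (per-depth similarity is exposed as an option; pooling
depths is the default because the depth treatment of this analysis is a
genuinely open choice), Spearman rho over vertices, Fisher z with |rho|
clipped at 1 − 10⁻¹² (finite arithmetic, order preserved).  The exact
sign-permutation test enumerates all 2ⁿ assignments (n ≤ 20; larger n
raises with a pointer to a Monte-Carlo alternative); p-values have
granularity 2⁻ⁿ and are never zero.

## Raster regression

Vertices are ranked by the sorting contrast's shape value (stable sort;
ties by vertex index) into contiguous near-equal bins (earlier bins take
the extras); per-bin means of the predicted contrast's shape are
regressed on per-bin means of the sorting shape (slope + intercept).
With one bin per vertex (the default) the statistics equal the unbinned
regression; binning exists for display, as does the Gaussian smoothing
along bins (FWHM = 1% of bin count, σ = FWHM/2.3548) which never feeds
statistics.

The estimator is leave-one-day-out: sorting values from one day, predicted
values from the other, the two fold slopes averaged per subject before the
group one-sample t-test (averaging rather than concatenating folds is a
package choice; the combination rule is not fixed by the procedure's
definition).  The suite demonstrates both halves of the rationale: planted
cross-contrast slopes are recovered without attenuation-relevant bias, and
self-sorting pure noise without the day split yields slope ≈ 1 while the
day-split estimator stays at 0 with a calibrated null t-test.

Note that with smooth (patchy) fields on small patches the *per-subject*
control-pair slope can be large by chance (few independent patches); the
control analysis is meaningful at the group level, where spurious slopes
have random signs.

## Pipeline

Stages (simulate, firstlevel, profiles, group, mvpa, raster, report)
communicate only through files in the output directory, so any stage can
be re-run in isolation and reproduces its outputs byte-for-byte for a
fixed configuration.  One config seed expands to per-stage sub-seeds via
a counter-based SeedSequence scheme; no hidden global randomness.  The
firstlevel stage is a demonstration-scale estimator check (a handful of
voxels) rather than a mass-univariate fit: the laminar analyses consume
the vertex-beta simulator directly, which is the level at which ground
truth is planted.

## Known limitations

* The equivolume construction is per-vertex 1D; curvature enters only
  through the inner/outer area proxies.
* The group model's exact reductions require the balanced design the
  package itself produces; unbalanced tables are rejected, not
  approximated.
* Decoding at desk scale easily saturates (accuracy 1.0), so depth trends
  in accuracy are only interpretable away from ceiling.
* The pattern-similarity contrast and the raster analyses assume a common
  vertex set across conditions and days; vertices with any missing depth
  are dropped globally per subject.
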