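# Methods

## Pipeline

`gaitdfa` classifies single gait trials into two conditions (shod vs
barefoot running) from 30 per-trial waveforms — {hip, knee, ankle} ×
{angle, moment, power} × {sagittal, coronal, transverse} plus the three GRF
components — and identifies the variables and frequencies that carry the
discrimination. The stages, all linear after feature extraction:

1. **Filtering.** Zero-lag (forward–backward) Butterworth low-pass, design
   order 4, cutoff 6 Hz for joint variables and 30 Hz for GRFs. The
   two-pass application squares the one-pass magnitude response and cancels
   phase lag; signals must exceed the 27-sample warm-up.
2. **Segmentation.** Heel strike = first vertical-GRF sample above the
   contact threshold (default 0.02 BW); toe off = first subsequent sample
   below it. A full cycle runs to the next supra-threshold rise (the next
   ipsilateral contact); when a recording holds only one stance, a
   stance-only span can be used (`cycle_mode`).
3. **Cycle normalisation.** Linear interpolation of the cycle span onto
   `n_samples` = 100 equally spaced points (endpoints included).
4. **Spectra.** One-sided modulus of the DFT, bins 0..49 (DC included —
   the mean level of a waveform is informative). With 100 samples the 50
   bins are the full one-sided band and the frequency axis is in cycles
   per gait cycle; converting to Hz requires the cycle duration and is
   deliberately left as metadata. The modulus discards the trial's absolute
   phasing: circularly shifted trials produce bit-identical feature rows,
   which is the property that lets trials share a feature space without
   temporal alignment. Flattening is variable-major, giving the
   trials × 1500 input matrix **M** (200 × 1500 at reference scale).
5. **PCA.** Covariance PCA (no variable standardisation, so variable
   scales matter — a property of the method, not an accident) computed by
   SVD of the centred matrix; eigenvalues use the n−1 normalisation.
   Retained rank k defaults to 10 (8 and 12 are the other conventional
   choices).
6. **DFA.** Two-class discriminant: solve S_B w = λ S_W w on the training
   PC scores, S_B the between-class scatter (rank 1 for two classes), S_W
   the pooled within-class scatter. Axis 1 attains the maximal variance
   ratio λ₁; axis 2 is the next generalized eigenvector. Trials project
   onto the 2-D DF plane; class centroids are computed from training
   trials only, keeping the predictive stage honest.
7. **Classification.** Distance ratio r = d(trial, shod centroid) /
   d(trial, barefoot centroid); r < 1 → shod, r > 1 → barefoot. r = 1 is
   exactly the decision boundary and is counted as an error (conservative;
   measure-zero for continuous data). With threshold 1 the rule is
   identical to nearest-centroid assignment, which the tests assert.
8. **Error accounting.** Overall error is the percentage of misassigned
   trials over *all* trials (training + predicted); training-only and
   prediction-only rates are reported alongside. Sensitivity = TP/(TP+FN)
   and specificity = TN/(TN+FP) with shod as the positive class; a ratio
   with an empty denominator is NaN, never silently 0.
9. **Subset optimisation.** Every r-of-n training-subject choice is one
   iteration (a subset and its complement are distinct); each refits PCA
   (training rows only, by default) and DFA and classifies everything.
   The minimum-overall-error subset wins; ties resolve to the
   lexicographically smallest subject set (and all ties are reported).
   The error histogram uses half-open 0.5-percentage-point bins — the
   error granularity of a 200-trial cohort.

## The two discriminant axes

With two classes S_B has rank 1: only DF 1 carries discrimination and λ₂ is
numerically zero, axis 2 being an arbitrary direction of the S_W-orthogonal
complement. The package keeps the 2-D DF plane (the scatter plots and the
distance ratio use both axes; the second adds an isotropic-ish component
that does not change nearest-centroid assignments materially) and reports
λ₂ so the imbalance is visible; `GaitDiscriminant(..., n_df_axes=1)`
restricts the centroid distances to DF 1 for anyone preferring the strictly
informative subspace. For the **variable contribution ranking**
the axes are combined with eigenvalue weights λᵢ/Σλ: an unweighted sum
would add the back-projection of an arbitrary unit vector (axis 2) to the
ranking key and measurably destroys the recovery of planted effects
(8–12/20 cohorts instead of 18–20/20 in our calibration runs). The
per-axis contribution columns and their plain sum remain in the output
table, so no information is hidden.

## Choosing k

k = 10 components per 100 training trials is the reference operating point,
and the package keeps that *ratio* when scaling down: desk-scale runs with
8 subjects (40 training trials) use k = 4. The ratio matters because the
discriminant is fitted in k dimensions from the training trials alone; at
k = 10 with only 40 training trials, chance separation of the training
classes is substantial (Mahalanobis ≈ √(k·(1/n₀+1/n₁))), which biases the
training half of the overall error well below 50 % even for data with no
condition effect, and gives a pooled fit enough capacity to absorb
heterogeneous (singular) response patterns. At the 1:10 ratio the null
calibration sits at chance (measured 47.9 % mean overall error across all
4-of-8 subsets under a zero planted effect, vs 41.6 % at k = 10) and the
optimisation benefit over pooled discrimination is expressed at every
scale.

## Numerical conventions

- **PCA sign**: each loading's largest-magnitude coefficient is made
  positive (eigenvector sign is otherwise arbitrary and would leak into the
  DF spectra). DF 1 is oriented so the shod centroid has a positive score;
  DF 2 by its largest-magnitude coefficient.
- **Ridge**: when cond(S_W) > 1e10, S_W gains ε·I with ε = 1e-8·tr(S_W)/k
  — small-sample insurance; never triggered at the design scales.
- **Weight normalisation**: DF weight vectors have unit Euclidean norm.
- **Fast enumeration engine**: `run_optimisation` computes each iteration's
  PC scores from the doubly centred training block of the precomputed
  trial × trial Gram matrix (top-k eigenvectors) and the cross-Gram block —
  algebraically identical to the SVD route up to per-component sign, to
  which assignments are invariant; the tests assert error-rate equality
  with the reference path. One full C(20,10) enumeration takes ≈ 4 min on
  one CPU. Results are bitwise independent of worker count and evaluation
  order, and a checkpoint CSV makes long runs resumable.
- **Degenerate iterations** (a training class with < 2 trials, zero
  training variance) are flagged with NaN errors and skipped by the
  arg-min and the histogram rather than aborting a long run.

## Synthetic cohorts

The generator emulates the *statistical* structure the pipeline consumes,
not musculoskeletal mechanics. Per variable, a base waveform is a sum of 6
cycle-locked harmonics with 1/h amplitude decay; subjects perturb harmonic
amplitudes and phases (sd `subject_effect_sd` = 0.2 — individual gait
signatures dominate), trials add smaller jitter plus white measurement
noise (sd `trial_noise_sd` = 0.05). The vertical GRF is a non-negative
double-peaked stance profile (impact + active peaks, ~2.4 BW) repeated at
the next ipsilateral contact so threshold event detection finds a full
cycle; AP/ML GRFs are stance-windowed oscillations. All variables share a
common magnitude scale by default because covariance PCA is
scale-sensitive; per-variable scales are configurable to probe exactly that
sensitivity.

The condition effect multiplies the harmonic amplitudes of the four
planted ankle-dominant variables (transverse-plane ankle angle and power,
sagittal ankle angle, coronal ankle moment) by 1 + e·cₕ, with the contrast
vector c normalised so the relative RMS amplitude change equals
`condition_effect_size`. Modulating existing harmonics (rather than adding
an independent random-phase component) keeps the effect first-order
visible in the modulus spectrum; an additive random-phase signature is
invisible to |DFT| whenever it lands phase-orthogonal to the base — a
property of modulus features worth remembering with real data too. The
default e = 0.35 was calibrated once so the planted variables are reliably
recoverable from the contribution ranking at the default cohort size
(20/20 seeded cohorts place all four in the ranking's top 6), while
leaving pooled discrimination clearly imperfect on cohorts with singular
subjects; real shod/barefoot ankle effects are of at least this relative
magnitude.

"Singular" subjects (the last `n_singular_subjects` ids — deterministic, so
the planted truth is a pure function of the config) deviate from the
generic pattern in one of two modes. `shuffled-variables` expresses the
effect in a subject-specific set of non-planted variables: such subjects
are hard to *predict* but harmless to *train on*, and because the overall
error counts every trial, the optimiser systematically prefers to absorb
them into the training set. `opposite-sign` reverses the effect: training
on such a subject actively misleads the discriminant, and the optimiser
excludes them (0/20 seeded runs place one in the best subset, against a
0.5 chance rate). The two modes therefore probe the two distinct reasons a
participant can be a poor training choice.

Randomness is one hierarchical seed tree (cohort → subject → condition →
trial): identical seeds are bitwise reproducible and adding trials does not
perturb existing ones.

**What passing tests do not show:** the generator's waveforms are
band-limited harmonic sums with Gaussian perturbations — no footwear-
specific timing shifts, no inverse-dynamics consistency between a joint's
angle, moment and power, no impact transients beyond the GRF profile, no
marker noise or soft-tissue artefact. Results on it validate the
*machinery* (the algebra, the bookkeeping, the optimisation logic and the
qualitative optimisation benefit), not the effect sizes to expect from
real cohorts.

## Problem sizes used in the shipped checks

Structural and statistical checks run at the reference design scale
(20 subjects, 200 trials, all 184,756 subsets, k = 10). Seed-averaged
statistical properties (null calibration, optimisation benefit) use
8-subject cohorts (70 subsets per seed, k = 4, 10–20 seeds), which keeps
each property a multi-seed measurement while the whole suite stays in the
minutes range.

## Limitations

- Two conditions only; the generalized eigenproblem is written for the
  rank-1 between-class case and multi-class DFA is out of scope.
- The exhaustive search is O(C(n, r)) end-to-end fits; beyond ~24 subjects
  use `refine_by_swap` (greedy, monotone, can stall above the exhaustive
  optimum — the tests quantify the gap on small cohorts).
- Cycle segmentation assumes a threshold-detectable vertical GRF; cohorts
  recorded without force data need events supplied upstream.
- The frequency axis is per-gait-cycle; comparisons across cohorts with
  very different cycle durations need that metadata.
- No C3D ingestion: trials enter as the documented CSV layout (the
  upstream motion-capture processing that produces waveforms is out of
  scope).
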