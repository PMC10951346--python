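# Methods

This note documents the models, conventions and defaults behind `tgckit`,
the choices made where the underlying analysis left them open, and what the
synthetic world does and does not establish.

## Theta-gamma coupling

**Modulation index.** For a phase series φ(t) (theta band) and amplitude
series A(t) (gamma band), phases are assigned to N equal bins on (−π, π],
the mean amplitude per bin is normalised to a distribution P, and
MI = (log N − H(P)) / log N with H the Shannon entropy. MI is invariant to
positive rescaling of the amplitudes (hence to recording gain) and lies in
[0, 1]. Empty phase bins receive an epsilon mass of 1e−12 before the
entropy (with a warning): this avoids log 0 while preserving the MI → 1
limit when all amplitude mass concentrates in one bin.

**Extraction.** Zero-phase (forward–backward) Butterworth band-pass filters
of order 4 each way, followed by the Hilbert analytic signal. Forward-
backward filtering avoids phase distortion, which would bias the phase
series directly. A transient region of 3 filter time constants
(τ = 1/(2π·theta bandwidth), ≈ 0.12 s at the 4–8 Hz default) is trimmed
identically from both series at each epoch edge; epochs must retain at
least 3 cycles of the theta low edge after trimming, and shorter epochs are
rejected with the minimum length in the error. Phase/amplitude are
extracted **per epoch** and pooled within a trial-result type before MI is
computed, so filter transients never span epoch boundaries.

**Defaults.** Theta 4–8 Hz, gamma 30–50 Hz, 18 phase bins. The source
analysis does not state its band edges, bin count or epoch windows; these
defaults follow the common convention for this MI estimator and the
literature this analysis descends from, and all are configuration, not
constants.

**Aggregation.** MI is computed per electrode and per N-back trial-result
type (target-correct, target-incorrect, nontarget-correct,
nontarget-incorrect), averaged over the nine frontal electrodes (an error
lists any missing one), then combined across trial types with weights equal
to each type's proportion of task epochs. Two weightings exist because the
verbal description of the published procedure ("multiply each MI by its
epoch percentage, then average the four values") implies division by 4:
`literal` (default) is mean(pᵢ·MIᵢ); `normalized` is Σpᵢ·MIᵢ, a convex
combination. The two differ by the constant factor 4 for every participant,
so group assignment at the derived cutoff is identical; the cutoff value
itself is scale-dependent, so the mode is stamped into every output. Trial
types with zero epochs contribute weight 0.

## Cognitive scoring

* **d′** = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate). Extreme rates 0 and 1 are
  replaced by 1/(2N) and 1 − 1/(2N) (N = the relevant trial count), the
  standard correction that keeps d′ finite; the source is silent on its
  correction.
* **Control-referenced z.** Each raw test score is standardised with the
  control group's mean and SD (ddof = 1). Trail Making A time per
  connection and the TMT B/A ratio are sign-flipped (larger raw = worse);
  all other battery scores are higher-is-better. Without these flips the
  processing-speed and executive composites would have inverted sign
  relative to the published group means.
* **Composites.** Domain composite = mean of available member-test z-scores
  (minimum 1 available, configurable); global composite = mean of the six
  domain composites, missing if any domain is missing.
* **Age norm.** OLS of control 2-back d′ on age; the age-corrected z divides
  the residual by the residual SD with denominator n−2 (regression degrees
  of freedom; n−1 selectable). A perfectly linear control set is rejected as
  degenerate rather than returning z = ±∞.
* **Impairment.** age-corrected z ≤ −1 ⇒ impaired; the boundary value is
  impaired.
* **Outlier screen.** One pass per variable on the combined patient sample:
  mean and SD computed once, values beyond 3 SD dropped and logged; never
  iterated. Participants flagged on TGC or the age-corrected z (the
  variables entering the cutoff derivation) are excluded from the analysis
  set; a flagged cognitive outcome is set missing for that participant
  only. Whether the source screened raw tests or composites is unstated;
  the screen here applies to the variables entering each analysis, and
  every removal is logged.

## Cutoff and effects

* **Youden index.** J = sensitivity + specificity − 1. The published
  formula omits the −1, but the reported indices (0.24 from 82%/42%; 0.2
  from 71%/49%) force the −1 form, which is also the field's standard
  definition; the maximiser is identical either way.
* **Orientation.** Low TGC predicts impairment (predicted-impaired ⟺
  tgc < c; "low" group ⟺ tgc < c; a value exactly at the cutoff is "high").
* **Candidate grid.** Midpoints between consecutive distinct sorted TGC
  values plus one candidate below the minimum and one above the maximum —
  this covers every achievable confusion matrix without using observed
  values as thresholds. Ties in J break toward the smallest candidate
  (deterministic; labels more participants high-TGC).
* **Cohen's d.** Pooled-SD standardiser; reported as magnitude with the
  direction carried separately, because the published table prints all d's
  unsigned and the comparison d_TGC − d_diagnosis is between magnitudes.
  Two identical degenerate groups give d = 0; zero pooled variance with
  unequal means is an error.
* **Summary tests.** Welch is the default t variant (the published age
  comparison reproduces only under Welch); Pearson chi-square uses no
  continuity correction (required to reproduce the published 2×2).

## Resampling

B = 5000 resamples of the n patients with replacement (matching the
published analysis); each resample re-derives the cutoff and recomputes all
statistics. Control norms, z-scores and impairment labels are fixed
participant attributes and are not refit inside iterations. CIs are 95%
percentile intervals. The cross-validation variant splits each resample
into a training half (⌊n/2⌋) that derives the cutoff and a validation half
(⌈n/2⌉) for evaluation. Iterations whose resample or half fails a
precondition (single-class labels; a split group below 2) are dropped and
counted, never imputed. A master seed spawns one `SeedSequence` child per
iteration, so any iteration is reproducible in isolation. Significance of
d_difference is read off its percentile CI (excludes 0 or not); the two d's
share a sample and are positively correlated, so overlap of their
individual CIs is not the test.

**Known limitation — bootstrap over-dispersion.** The Youden cutoff is a
non-smooth functional of the empirical distribution, and the naive
bootstrap over-disperses such statistics: on synthetic cohorts the bootstrap
SD of d_difference exceeds the true across-cohort sampling SD by roughly
half again, so percentile CIs are conservative (empirical coverage at the
top of, and marginally above, the nominal range in our coverage test). The
very wide interval this method prints for d_difference is therefore a
property of the procedure, not only of the data.

## Synthetic world

A single latent prefrontal-function factor L ~ N(0,1) drives TGC
(T = 0.0018 + a·L + noise, total SD 0.0012, clipped at 1e−6 since MI is
non-negative), every battery test (z-scale score = patient deficit +
λ_domain·L + noise, mapped through plausible control means/SDs and the
direction flips), and 2-back d′ (base 2.0 at age 71.5, −0.03/year,
patient deficit −0.8, slope 0.5 per latent unit, noise SD 0.5). Diagnosis
(MCI vs MCI+rMDD) is assigned independently of L with a common deficit
(−0.8 z), so the population diagnosis effect is exactly zero while the TGC
median split has a closed-form population d on the global composite
(solved loadings make it 0.6 by default — the scale of the published
effect). N-back counts come from an equal-bias signal-detection model with
60 targets / 120 non-targets (trial counts are not published; these are
declared defaults). Group sizes, patient ages, the TGC marginal and the
patient deficits reproduce the published descriptive table; the control age
distribution (71.5 ± 6.0) is a declared choice since controls' demographics
are not printed.

The EEG generator produces s(t) = A(t)·sin(2πf_γt) + sin(2πf_θt) + white
noise with A(t) = a_γ[(1−χ) + χ(1+cos(2πf_θt))/2]: χ = 0 is an uncoupled
control, χ = 1 full modulation, with MI monotone in χ. It does not emulate
blinks, muscle artifact, 1/f background, volume conduction or non-sinusoidal
rhythms — so a green MI test establishes correctness of the estimator on
clean parametric coupling, not robustness to real recording artifacts.
Likewise the cohort generator's single-factor linear-Gaussian structure
establishes that the pipeline recovers planted effects and that its CIs
behave as designed, not that the published effect sizes are correct.

## Determinism

Every stage draws from `numpy.random.SeedSequence` children of one integer
seed (counter-based splitting), pipeline artifacts embed a hash of the
resolved configuration, contain no timestamps, and identically-seeded runs
are byte-identical.
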