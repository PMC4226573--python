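# Methods

## Signal model

A radial artery pressure waveform (RAPW) beat, resampled to 1000 samples and
min–max scaled to [0, 1], is modeled as the superposition of three positive
Gaussian sub-waves

    f(n, x) = Σₖ Hₖ exp(−(n − Cₖ)² / (2 Wₖ²)),   n = 1 … 1000,  k = 1, 2, 3,

with peak heights Hₖ > 0, width scales Wₖ > 0 and ordered peak positions
1 < C₁ < C₂ < C₃ < 1000. Physiologically, the first sub-wave represents the
forward (ejection) component, the second the main reflected component
returning from the periphery, and the third a late reflection / diastolic
component. Wₖ is parameterized as the Gaussian standard-deviation-like
scale; a full-width-at-half-maximum convention would be a pure rescaling
(factor 2√(2 ln 2)) and would change neither Cₖ nor Hₖ, hence none of the
reported indices.

Reflection is summarized by the peak position interval
`C_ref-forw = C₂ − C₁` (samples on the normalized beat axis, i.e. a
dimensionless fraction of the beat × 1000 — not milliseconds) and the peak
height ratio `H_ref/forw = 100·H₂/H₁` (%). Per subject, C₁, C₂, H₁, H₂ are
arithmetic means over the selected episodes and the derived indices are
computed **from the averaged values** (ratio of means, not mean of ratios);
the difference is second-order for the beat-to-beat variability considered
here, and the ratio-of-means form is numerically consistent with the group
tables used for parameterization (e.g. 0.77/0.61 → 126%).

One caveat on heights: amplitude normalization subtracts the episode
minimum, so the fitted Hₖ of a normalized pulse are not the raw-scale
sub-wave heights; they are heights on the normalized scale, where part of
the diastolic floor is absorbed into the decomposition. All height indices
are therefore comparable within and across subjects analyzed by the same
pipeline, which is how they are used.

## Fitting

The objective is the sum of squared errors Σₙ (S(n) − f(n, x))² over all
1000 samples (RMSE = √(SSE/1000) is reported alongside for diagnostics).
Minimization uses a two-stage particle swarm optimizer authored in the
package:

- **Stage 1** — global PSO over the full box (defaults: swarm 40,
  150 iterations, inertia decaying linearly 0.9 → 0.4, cognitive = social
  = 1.5). Particle positions are clipped to bounds; peak positions are
  sorted at initialization (feasibility repair), and ordering violations
  during flight incur an additive penalty (10⁴ per unit violation plus a
  fixed offset), large relative to the attainable SSE (< 10³) so infeasible
  particles never become global bests.
- **Stage 2** — restart around the stage-1 best with every bound contracted
  to ±10% of the parameter's full range, 50 iterations.
- **Polish** (default on) — bounded trust-region least squares
  (`scipy.optimize.least_squares`) from the swarm best; the result is
  re-sorted and accepted only if feasible and at least as good.
- **Adaptive restarts** — the three-Gaussian SSE landscape has a prominent
  local optimum in which two model components merge and the third collapses
  to its height floor (residual RMSE ≈ 0.026 on clean pulses, versus ~0 at
  the global optimum). A single run falls into it on roughly half of the
  seeds for some shapes, so the optimizer reruns the full two-stage schedule
  from fresh initializations (derived seeds, up to 6) until the RMSE reaches
  0.02 — the noise ceiling the pretreatment stage is specified for — keeping
  the best run. All randomness flows from one integer seed, so fits are
  exactly reproducible.

Default bounds: H ∈ (0.01, 1.2) (normalized amplitude ≤ 1 plus headroom),
W ∈ (10, 300) samples, C ∈ (2, 999). Whether H should be capped at 1 is
left open; the 1.2 ceiling never binds on realistic pulses.

Batches fit each episode independently with a per-episode seed derived from
(batch seed, episode index) by default, making results independent of
scheduling; a content-hash seeding mode makes them additionally invariant
to episode order.

For oracle testing, the fitted objective is checked against an independent
scalar-loop summation (10⁻¹² agreement) and, on two-parameter reductions,
against exhaustive grid search.

## Pretreatment

- **Baseline removal**: zero-phase (forward–backward) 4th-order Butterworth
  high-pass at 0.05 Hz, with reflection padding of ~2 filter time constants.
  Zero-phase filtering avoids phase-distorting beat morphology. A 0.05 Hz
  high-pass only behaves as designed on records spanning several cutoff
  periods (the protocol records ≥ 1 min); on very short records a slow bow
  remains, which downstream stages tolerate because foot detection is
  offset-invariant and normalization is amplitude-affine-invariant.
- **R-peak detection**: band-pass (5–30 Hz) energy envelope, relative
  threshold (30% of the envelope maximum), 0.25 s refractory period, with
  refinement to the local ECG maximum. This is a generic timing-anchor
  detector, not a reimplementation of any published wavelet detector; R-peaks
  serve only to anchor beat windows.
- **Pulse-foot detection**: per beat, the maximal-upslope point is located
  on a 15 ms-smoothed copy and the intersecting-tangent construction
  (tangent at maximal upslope ∩ horizontal through the preceding minimum)
  brackets the onset; the foot itself is then estimated by least-squares
  fitting a continuous two-segment model — linear diastolic trend plus a
  rising edge with an optional sharp onset step — whose breakpoint is the
  foot (a parametric rising-edge fit). A record-level consistency pass
  exploits the physiological stability of the foot-to-R-peak transit time:
  feet deviating more than 5 samples from the record median offset are
  re-fit in a narrow window and, failing that, snapped to the consensus.
  On synthetic trains this chain is accurate to ±5 samples for additive
  noise SD up to 0.02 (≈ 3% of pulse amplitude).
- **Ectopic exclusion**: an RR interval deviating > 20% from the running
  median RR (centered 7-interval window) flags both bounding beats.
  Threshold and window are configuration keys. This is an operational
  stand-in for dedicated ectopic classifiers — sufficient for timing-based
  exclusion, not rhythm diagnosis.
- **Episode selection**: the earliest run of 10 consecutive unflagged beats;
  episode i is the half-open sample range [footᵢ, footᵢ₊₁) (0-based
  indexing throughout), so concatenated episodes reproduce the spanned
  signal exactly. Ten beats are used so that variation over a respiratory
  cycle is represented in the average.

## Normalization

Width normalization resamples an episode onto 1000 uniformly spaced points
by linear interpolation (cubic available); the grid spans the episode, so
endpoints are preserved, and linear interpolation preserves the monotone
rising edge. Amplitude normalization is the min–max map
(x − min)/(max − min). Width runs first, then amplitude. Whether the
original procedure interpolated or repeated/dropped samples is not
documented; linear interpolation is this package's choice.

## Synthetic data

The generator produces the structures the analysis assumes, not general
physiology:

- **Beats** are exact three-Gaussian curves. Defaults
  H = (0.73, 0.67, 0.30), W = (55, 85, 200), C = (136, 260, 450) place the
  forward and reflected peaks at the reference cohort's normotensive group
  means; the third sub-wave is deliberately wide so the diastolic limb keeps
  a definite decay to the beat's end, making the next onset well defined
  (real radial pulses decay through end-diastole; a narrow third Gaussian
  would leave an unphysiological flat segment).
- **Trains** concatenate per-beat curves rescaled to a jittered RR series
  (default 0.9 s ± 0.02 s), add sinusoidal baseline wander (< 0.05 Hz) and
  white noise, and place a spike-template ECG channel 200 ms before each
  foot. The ECG is a timing template only. Ectopic beats are modeled as a
  40% RR shortening — enough to exercise the exclusion rule, with no claim
  about ectopic morphology. A shape-jitter knob (default 0, i.e. off)
  perturbs the sub-wave parameters per beat to exercise episode averaging;
  a generic low-frequency amplitude modulation is *not* claimed to model
  respiration.
- **Cohorts** draw per-subject index values independently per
  (sex × SBP-category) cell from normal distributions. The default
  parameterization is a 190-subject layout (cell sizes 22/29/33/21 men,
  17/25/25/18 women) with per-cell means/SDs for C₁, C₂, C_ref-forw, H₁,
  H₂, H_ref/forw, SBP and DBP. Because each index is drawn independently,
  cross-index correlations within subjects are absent — adequate for the
  per-variable ANOVA, not for multivariate analyses. A waveform-level
  cohort mode simulates full recordings per subject (used for end-to-end
  tests at reduced n, default 20 subjects × 14 beats with the reduced fit
  settings below).

Consequently, passing tests demonstrate correct recovery and inference
**under the model's own assumptions** (Gaussian beats, stationary shapes,
white noise, sinusoidal wander, normal cell distributions); they do not
certify performance on pathological morphologies, motion artifacts, or
non-Gaussian beat shapes.

## Statistics

SBP readings are rounded to integers (half-to-even, so 130.5 stays in
121–130) and binned with inclusive boundaries ≤110 / 111–120 / 121–130 /
≥131 mmHg. MAP = DBP + (SBP − DBP)/3 and PP = SBP − DBP use the mean of the
two cuff readings.

Each variable is analyzed with a two-way fixed-effects ANOVA (sex,
SBP category, interaction) via OLS. For the unbalanced layout the
sum-of-squares type matters; Type III with sum-to-zero coding is the
default (matching the convention of mainstream clinical statistics
software), Type II is available by flag. Significance is bucketed
NS / P<0.05 / P<0.01 with the a-priori threshold 0.05; no multiple-testing
correction is applied across the six indices, by design. Degenerate cases:
a zero-variance response returns F = 0, p = 1 for every effect (the 0/0
limit); empty design cells raise an explicit design error; single-subject
cells report SD 0 with a warning.

Calibration: under a null cohort (all cells identically distributed) the
empirical rejection rate at 0.05 is verified to lie in [0.03, 0.07] over
2000 replicates.

## Problem sizes and reduced settings

End-to-end cohort runs (pipeline, determinism checks) use 20 subjects ×
14 beats and a reduced swarm (24 particles, 60 + 20 iterations) — at the
pipeline's noise level (0.005) these fits reach the same optima as the full
settings, and the package's own choice is to keep full-cohort runs in the
tens of seconds. Parameter-recovery validation uses the full defaults
(swarm 40, 150 + 50). The ANOVA reproduction uses 200 seeded cohort
replicates; type-I calibration uses 2000.

## Known limitations

- The three-Gaussian model is descriptive; sub-wave-to-physiology mapping
  (forward/reflected) is an interpretation, not a mechanistic decomposition.
- Foot detection's transit-time consistency pass assumes a stable pulse
  transit time within a record; records with genuine beat-to-beat transit
  variability beyond ±5 ms would have that variability suppressed.
- Height indices live on the normalized amplitude scale (see above); they
  are not absolute pressures.
- The cohort generator draws indices independently; it cannot exhibit
  within-subject correlations between indices.
- WFDB-format records are not read; raw records are two-column CSV with a
  JSON sidecar carrying the sampling rate.
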