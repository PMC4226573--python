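# pulsedecomp

Gaussian decomposition of radial artery pressure waveforms (RAPW) for
quantifying arterial wave reflection, with cohort-level statistics.

The arterial pulse recorded at the wrist superposes a **forward** wave
(ventricular ejection) and a **reflected** wave returning from peripheral
reflection sites. Early or large reflections raise central systolic load and
are a recognized cardiovascular risk marker. `pulsedecomp` quantifies
reflection by decomposing each beat into three positive Gaussian sub-waves

```
f(n, x) = Σₖ Hₖ · exp( −(n − Cₖ)² / (2 Wₖ²) ),   k = 1, 2, 3,   1 < C₁ < C₂ < C₃ < 1000
```

on a normalized beat axis (1000 samples, amplitude min–max scaled to [0, 1]).
The first Gaussian is read as the forward component, the second as the main
reflected component, giving four base indices — peak positions `C₁`, `C₂`
and heights `H₁`, `H₂` — and two derived reflection indices:

- `C_ref-forw = C₂ − C₁` — reflection timing (samples of the normalized beat);
- `H_ref/forw = 100 · H₂ / H₁` — reflection amplitude relative to the forward wave (%).

The nine parameters are estimated per beat by minimizing the sum of squared
errors with a **two-stage particle swarm optimizer** (global stage over the
full parameter box, then a restart stage in a contracted box around the
stage-1 best, plus an optional local least-squares polish). Per subject, the
indices are averaged over ten consecutive ectopic-free beats, and effects of
blood pressure and sex are tested with a two-way (sex × SBP-category) ANOVA,
Type III sums of squares.

The package is aimed at physiological-signal researchers who want a tested,
reproducible reference implementation of this analysis — including a
synthetic-data module that generates both beat-level signals (ECG + pressure
trains with known sub-wave parameters, baseline wander, noise, ectopic
beats) and cohort-level index tables, so the entire chain is verifiable
without access to clinical recordings.

## Worked example

Simulate one subject's recording, run the full pretreatment → normalization
→ fitting → indices chain:

```python
from pulsedecomp import (
    PulseGroundTruth, TrainSpec, FitConfig,
    generate_pulse_train, remove_baseline, detect_r_peaks, detect_pulse_feet,
    exclude_ectopic, segment_and_select, normalize_episode,
    fit_episode_batch, compute_indices, compute_pressures,
)

gt = PulseGroundTruth(noise_sd=0.01, baseline_amp=0.1)      # known sub-waves
train = generate_pulse_train(gt, TrainSpec(n_beats=15, seed=42))
rec = train.record

rapw = remove_baseline(rec.rapw, rec.fs)                    # drop 0–0.05 Hz wander
ecg = remove_baseline(rec.ecg, rec.fs)
r_peaks = detect_r_peaks(ecg, rec.fs)                       # beat anchors
feet, ok = detect_pulse_feet(rapw, rec.fs, r_peaks)         # beat onsets
mask = exclude_ectopic(r_peaks, rec.fs) | ~ok               # timing outliers
episodes = segment_and_select(rapw, feet, mask, k=10)       # first 10 clean beats
pulses = [normalize_episode(ep) for ep in episodes]         # 1000 samples, [0, 1]
fits = fit_episode_batch(pulses, FitConfig(seed=7))         # swarm fit per beat
idx = compute_indices(fits)                                 # average over beats
bp = compute_pressures([104, 106], [67, 69])                # paired cuff readings

print(f"C1 = {idx.C1:.1f}, C2 = {idx.C2:.1f} (samples of the normalized beat)")
print(f"C_ref-forw = {idx.C_ref_forw:.1f} samples")
print(f"H_ref/forw = {idx.H_ref_forw:.1f} %")
print(f"MAP = {bp.MAP:.1f} mmHg, PP = {bp.PP:.0f} mmHg")
```

Output:

```
C1 = 136.4, C2 = 258.3 (samples of the normalized beat)
C_ref-forw = 121.8 samples
H_ref/forw = 92.4 %
MAP = 80.3 mmHg, PP = 37 mmHg
```

The ground truth placed the forward peak at 136 and the reflected peak at
260, so the recovered timing indices are within ~2 samples (0.2% of the
beat) despite noise, baseline wander and the detection/normalization chain.
`C_ref-forw ≈ 122` says the reflected wave peaks about 12% of a beat after
the forward wave; `H_ref/forw ≈ 92%` says its amplitude is slightly below
the forward wave's. Heights are reported on the normalized [0, 1] amplitude
scale (see `docs/methods.md`).

Cohort-level analysis, from the command line:

```
pulsedecomp simulate --mode cohort --seed 3 --out cohort.csv
pulsedecomp anova --cohort cohort.csv --out-anova anova.csv --out-summary summary.csv
```

which prints, per index and effect, F, degrees of freedom, p and an
NS / P<0.05 / P<0.01 bucket. On the default 190-subject parameterization
the SBP-category main effect on `C_ref-forw` is strongly significant while
the sex effect and the interaction typically are not. A full end-to-end run
(waveform simulation through ANOVA) is `pulsedecomp run-all --outdir out/`.

## Layout

- `src/pulsedecomp/synthetic.py` — beat-, train- and cohort-level generators
- `src/pulsedecomp/preprocessing.py` — baseline removal, R-peak/foot detection, ectopic exclusion, episode selection
- `src/pulsedecomp/normalization.py` — width (1000 samples) and amplitude ([0, 1]) normalization
- `src/pulsedecomp/gaussfit.py` — three-Gaussian model, SSE objective, two-stage PSO
- `src/pulsedecomp/indices.py` — per-subject reflection indices, MAP/PP
- `src/pulsedecomp/stats.py` — SBP categorization, two-way ANOVA, group summaries
- `src/pulsedecomp/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, CSV/JSON contracts
- `docs/methods.md` — model, assumptions, numerical choices, limitations
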