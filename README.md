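# shadowcue

Simulation and analysis of a virtual-reality psychophysics paradigm probing
how the reliability of cast shadows reweights the use of **image-based**
(2-D luminance) versus **object-based** (3-D structure) edge cues in fast
orientation discrimination.

An observer walks a 6 × 6 × 3 m room filled with ten textured boxes.  Every
few seconds a small oriented probe — 16 superimposed gratings windowed by a
~3° disc — is inserted either at a luminance-defined edge (*image-driven*)
or a depth-defined object boundary (*object-driven*), and the observer
judges whether its orientation is congruent or incongruent with the local
scene orientation.  Shadows follow one of three regimes: *reliable* (one
fixed light per block), *unreliable* (a new light azimuth before every
probe) or *absent* (ambient only, doubled).  `shadowcue` reimplements the
full computational stack of this paradigm — scene rendering, probe
insertion, session bookkeeping, behavioral analysis, and the
cue-combination observer model — with a synthetic observer of known ground
truth in place of human participants, so every stage is testable with no
external data.

## The model

Behavior is summarized with equal-variance signal detection theory
(congruent = signal):

    d′ = Φ⁻¹(p_hit) − Φ⁻¹(p_fa)        c = −[Φ⁻¹(p_hit) + Φ⁻¹(p_fa)]/2

and the primary effect measure is ΔSensitivity = d′(image-driven) −
d′(object-driven).  The observer model extracts orientation/energy maps
from the pre-probe image snapshot, the depth snapshot, and the probe-present
snapshot with quadrature Gabor pairs (8 channels); forms two differential
maps as pixel-wise circular orientation distances to the probe map; mixes
them with a cue weight *w*,

    incongruency = w · Δ_image + (1 − w) · Δ_object ,

pools the result over a 3 × 3 box at the probe location, and answers
"incongruent" iff the pooled value exceeds 45°.  The weight *w* is fitted
by maximizing trial-by-trial agreement between model and observer responses
over a grid, with bootstrap resampling of trials.

## Worked example

Simulate two 11-observer cohorts (reliable shadows, stationary *w* = 0.45,
versus unreliable shadows with *w* drifting 0.45 → 0.75 across each block),
then fit the cue weight and run the behavioral analysis:

```
python analysis/02_simulate_cohorts.py           # ~15 min; writes results/trials_cohorts.csv
python analysis/03_fit_cue_weight.py
python analysis/04_behavioral_analysis.py
```

The fitting step prints:

```
reliable    w_best=0.40  bootstrap 95% CI [0.34, 0.46]  peak agreement 0.804
unreliable  w_best=0.58  bootstrap 95% CI [0.50, 0.71]  peak agreement 0.806

parameter recovery (fresh trial bank):
  w_true=0.2: median w_hat=0.18, median |error|=0.040
  w_true=0.5: median w_hat=0.49, median |error|=0.045
  w_true=0.8: median w_hat=0.80, median |error|=0.060
```

The reliable cohort, generated with slightly object-leaning weight, is
recovered below 0.5; the drifting cohort's time-averaged weight lands above
0.5 — the two configurations straddle equal weighting, and fits of
responders with known *w* are accurate to a few hundredths.  The analysis
step then reports per-configuration paired Wilcoxon tests on the diagonal
shift d′ − c (image vs object, 3× Bonferroni), early/late split-half
ΔSensitivity with across-observer confidence intervals, and the 2-minute
sliding-window time course (`results/*.csv`, `results/*.json`).

## Layout

```
src/shadowcue/      scene, probe, observer, responder, session, sdt, studies, io
analysis/           numbered narrative drivers (render, simulate, fit, analyze)
tests/              unit/property suite + end-to-end acceptance checks
docs/methods.md     model, parameters, calibrations, design choices, limitations
```
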