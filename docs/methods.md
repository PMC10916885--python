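# Methods

`shadowcue` simulates and analyzes a virtual-reality psychophysics paradigm
that asks how the reliability of cast shadows reweights the use of
image-based (2-D luminance) versus object-based (3-D structure) edge cues in
a fast orientation-discrimination task.  Every stage of the original
computational stack is reimplemented: procedural scene generation and
rendering, probe synthesis and insertion, session orchestration, a synthetic
observer with known ground truth, signal-detection analysis, and the
cue-combination observer model with agreement-based fitting of the cue
weight *w*.  A synthetic responder replaces human participants so that every
stage is testable without any external data.

## Virtual world and rendering

The room is 6 × 6 × 3 m, all interior surfaces carrying a binary black/white
zigzag wallpaper: stripes ~0.70 m wide running at ±45°, reversing direction
every ~1.5 m (implemented as a triangular-wave shear with unit slope of the
stripe coordinate).  Eleven box specifications are drawn by sequential
rejection sampling — footprint 0.40–1.20 m per side, height 0.40–2.40 m,
rotation uniform in [0°, 180°), centers at least 0.80 m from the room center
and from each other — and ten are instantiated; the eleventh location is
reserved as the target of the end-of-block memory displacement.  Box
textures are the wall pattern scaled down by 2.

Snapshots are rendered by a vectorized pinhole ray caster at the analysis
resolution of 90 × 100 px (width × height) covering 45° × 50°, producing an
aligned luminance map and metric depth map (nearest hit along each ray).
Shading is ambient (0.30) plus Lambertian diffuse (0.60) under a directional
light at 45° elevation, with hard shadows cast by the boxes only; in the
*absent* configuration the directional term is removed and ambient is
doubled, which compensates the mean (but deliberately not the range) of the
luminance distribution.  The diffuse:ambient ratio of 2 was chosen so that
doubling ambient approximately equals the mean diffuse contribution
(E[cos⁺·visibility] ≈ 0.4 over interior surfaces); the ambient-compensation
property is tested at a 25 % relative tolerance, reflecting that the match
is approximate by design.  Albedos are 0.10/0.90 for the black/white
stripes.  Luminance is dimensionless in [0, 1]; no attempt is made to match
photometric units, which were only indicative in the original setup.

The session pipeline renders at 2× the analysis resolution and
block-averages down, and converts the depth map to a min-max-normalized
8-bit intensity image before analysis.  Both steps emulate the capture
chain of the original experiment (high-resolution headset frames
downsampled to 90 × 100; depth stored as a gray-scale image whose intensity
scales with distance) and are load-bearing: without anti-aliasing, oblique
wallpaper edges are stair-stepped and their pixel-level orientation is
unreliable; without quantization, the depth map is featureless on smooth
surfaces and roughly half of the image-driven trials lose their pooling-
region energy.  `render_snapshot` with `supersample=1` remains the exact
per-pixel ray cast used by the geometric oracle tests.

Navigation is emulated by a seeded random-waypoint walk (0.7 m/s, eye
height 1.6 m, pitch bounded at ±30°, waypoints rejected inside boxes).
Light schedules: *reliable* draws one azimuth per block; *unreliable*
redraws the azimuth before every probe; *absent* has no directional term.

## Probe and insertion

The probe is a disc of ~3° diameter with a Gaussian edge (SD 15 arcmin)
carrying 16 superimposed gratings at 11.25° spacing, frequency ~1.2
cycles/°, random uniform phases.  The amplitude vector is **a** = **n** +
**s**: **n** i.i.d. Gaussian contrast noise (negative draws clipped at 0)
and **s** zero except 40 % contrast at the component aligned with
(congruent) or orthogonal to (incongruent) the reference orientation.  The
nominal noise level of 3 % ± 1 % was adjusted in the original task per
participant to hold performance at threshold (d′ ≈ 1); the synthetic
observer is far less noise-limited than a human at the nominal level, so
the same calibration was run for this pipeline (noise mean scanned at a
fixed 3:1 mean:SD ratio, pooled d′ at *w* = 0.5 under reliable shadows) and
the default frozen at mean 0.15, SD 0.05 (pooled d′ ≈ 1.05).

Insertion points are selected on Sobel edge maps of the image and depth
snapshots: both maps min-max normalized; the modulator blurred (Gaussian SD
5 px, truncated at 4 SD, reflected borders) and inverted; the driver
corrupted with per-pixel U(0, 0.2) noise; Harris corners of the driver
(3 × 3 Sobel gradients, 10 × 10 box window, k = 0.04; top 10 % of the
response) set to zero; the product of driver and modulator windowed by a
central soft disc (diameter 80 % of image width, Gaussian edge SD 10 % of
width); the probe lands on the argmax, with its orientation read from the
driver's Sobel orientation there.  Ties break to the lowest (row, col)
index.  The session layer additionally zeroes a 6-px border so the probe
patch and the model's 3 × 3 pooling box always have full support.  Pixel
coordinates are 0-based (col, row), origin top-left; orientations are
degrees in [0°, 180°), 0° = horizontal edge, shared by every module.

## Observer model and cue-weight fitting

Orientation/energy maps come from quadrature Gabor pairs at eight
orientations: envelope SD 2 % of image width for scene maps and 1 % for the
probe map; per pixel, energy = even² + odd² and the orientation is the
channel of maximal energy.  The even kernel's DC is removed so constant
inputs yield exactly zero energy.  The carrier's nominal tuning is ~1
cycle/degree; a period of 2 % of image width (1.8 px) would put several
channels above the Nyquist limit, where the sampled kernels for the 67.5°
and 112.5° channels alias onto each other's orientation, so the period is
set to 2.5 % of width (2.25 px, 0.89 cycles/°) — the closest alias-free
value to the nominal tuning.

Per trial, the pixel-wise circular orientation distance of each scene map
to the probe map forms two differential maps in [0°, 90°]; they are mixed
as *w*·image + (1 − *w*)·object, averaged over the 3 × 3 box at the probe
location, and compared with 45°: above → "incongruent", otherwise
"congruent" (a pooled value of exactly 45° counts as congruent and is
logged).  A trial is excluded when any required energy map has channel-max
energy below max(10⁻⁹ × its global maximum, 10⁻²⁰) at every pixel of the
pooling box; the exclusion is symmetric in the two cues and independent of
*w*.  The synthetic exclusion rate (~5–7 %) is a property of these scene
statistics and is not matched to the ~30 % reported for the original data.

The cue weight is fitted by maximizing trial-by-trial agreement between
model and observer responses over a grid (default 0–1 in steps of 0.01;
ties resolve to the midpoint tied index), with bootstrap resampling of
trials (default 1,000) to characterize the argmax distribution.  Excluded
trials drop out of both numerator and denominator.

## Synthetic observer

The responder answers through the same decision variable *v* (pooled
incongruency at its current weight), softened by logistic noise in the
incongruency domain: P(incongruent) = σ((v − 45°)/τ) with τ = 8° by
default; τ → 0 recovers the hard rule.  Lapses (default 2 %) produce a fair
coin, invalid responses (default 3 %) emulate missed response windows, and
model-excluded trials are answered by a coin flip, since an observer always
answers even when the model has no decision variable.  An optional linear
schedule drifts *w* from a start to an end value between an onset time and
the block end, emulating the minutes-long reweighting under degraded
shadows.  Memory-task outcomes are Bernoulli (default accuracy 0.75, the
threshold regime of the dual task; 0.5 is the two-alternative chance
level).

## Sessions and analysis

A block is 100 probe trials at inter-trial intervals uniform on
[2.0, 3.6] s (~5 min), with insertion type and congruency each drawn 50/50
per trial (the 50/50 congruency base rate makes d′/criterion estimation
well-posed and is logged).  Four consecutive incorrect/invalid responses
scramble the box configuration (not after the final trial, whose room feeds
the memory task).  After trial 100, one random box moves to the spare
location preserving size and rotation, the memory question is answered, and
the score doubles (correct) or halves (incorrect) the count of correct
sensory responses.  Memory-only blocks last 30 s and contain no probes.
Sessions interleave the shadow configurations in per-observer seeded
balanced order and write a master CSV trial log that also carries each
trial's pooled differential statistics — the sufficient statistics the
cue-weight fit consumes.

Analysis treats congruent trials as signal: d′ = Φ⁻¹(p_hit) − Φ⁻¹(p_fa),
c = −[Φ⁻¹(p_hit) + Φ⁻¹(p_fa)]/2, with 0/1 proportions corrected by 1/(2N);
the diagonal shift is d′ − c (implemented literally, not scaled by 1/√2).
Invalid responses are excluded everywhere.  ΔSensitivity =
d′(image-driven) − d′(object-driven) is tracked by a sliding window
(default 2 min, 10 s step, ≥10 valid trials per type per window; windows
failing that return an insufficient-data marker rather than raising) and by
early/late half-block splits, pooling within observer × configuration
before averaging across observers.  Configuration contrasts use paired
Wilcoxon signed-rank tests on per-observer diagonal shifts with 3×
Bonferroni correction, alongside a two-way repeated-measures ANOVA.

## Study designs and problem sizes

`parameter_recovery` validates the fit: a bank of fully rendered pipeline
trials (10–12 blocks ≈ 1,000 included trials) is built once; each replicate
draws 3,000 trials from the bank with replacement — stratified so at least
30 % carry cue conflict (a decision that flips somewhere inside
*w* ∈ [0, 1]) — answers them with a responder of known *w*, and refits.
Recovery is accurate to a median |ŵ − w| ≤ 0.06 for *w* ∈ {0.2, 0.5, 0.8}.

`two_cohort_study` runs 11 observers × 2 blocks per configuration
(200 trials per observer per configuration, mirroring the per-configuration
counts of the original cohort): a reliable-shadow cohort stationary at
*w* = 0.45 versus an unreliable-shadow cohort drifting 0.45 → 0.75 across
the block.  The drift moves the drifted cohort's late-block ΔSensitivity in
the predicted direction relative to the reliable cohort (late-half median
difference ≈ +0.4 d′ units at these sizes).  The *absolute* ΔSensitivity
level, however, is negative at every *w* in this world: box silhouettes are
simultaneously depth and luminance edges, so object-driven trials enjoy a
twin-cue advantage that wallpaper (image-only) insertions lack, and the
simulated ΔSens(*w*) curve runs from about −0.9 (*w* = 0.45) to −0.2
(*w* = 0.9) without crossing zero.  The corresponding end-to-end
acceptance check therefore fails at its stated anchors, and is kept
failing rather than re-tuned; the limitation is a property of these scene
statistics (hard shadows, no interreflection, clean silhouette shading),
not of the reweighting machinery, which the recovery study validates.

## What the synthetic data do and do not show

The generator emulates the structure of the paradigm — aligned image/depth
captures, driver/modulator insertions, threshold-calibrated probes,
block/session bookkeeping, observers with controllable cue weights — and
makes every analysis stage testable against known ground truth.  It does
not emulate photometric calibration, head-motion dynamics, binocular
presentation, engagement fluctuations, or the statistics of real
human responses; passing tests demonstrate correctness of the pipeline and
recoverability of its parameters under these synthetic conditions, not
reproduction of human effect sizes.

## Numerical choices and degenerate inputs

Seeds flow from named `numpy` `SeedSequence` streams; every stage is
deterministic given its seed (a full simulate → fit → analyze run is
byte-reproducible).  Gaussian blurs truncate at 4 SD with reflected
borders.  Sobel magnitudes below 64 ε of the input scale snap to zero, and
orientation is undefined (NaN) at zero gradient; selecting such a point
raises a degenerate-map error, as does a constant driver map.  A constant
modulator map normalizes to zeros (no suppression) rather than raising.
The walker advances in 0.5 s steps past viewpoints whose scene cannot
support an insertion (featureless view, border argmax), and steps out of
boxes that a scramble may have placed on its path.
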