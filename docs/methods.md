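# Methods

This note documents the models behind `wormquant`, the operational
definitions it fixes where the underlying assays are scored by eye or by
external tracker scripts, the defaults and why they were chosen, and what
the synthetic generators do and do not emulate.

## Ratiometric calcium quantification

The analysis assumes two-channel (CFP donor / YFP acceptor) recordings of a
FRET calcium indicator in a single cell body, nominally at 10 Hz.

**ROI tracking.** The ROI is a rectangle whose pixel realization covers the
pixels with centres inside `center ± half` per axis; the resulting block
dimensions are frozen when the ROI is created and kept constant along the
tracked path, so the pixel count (and hence the decile size) never changes
mid-recording. For each frame after the first, the summed two-channel image
restricted to the previous frame's ROI is background-subtracted with the
decile rule, negative residuals are clipped to zero (a negative weight
would let a dim corner pull the centroid outside the ROI), and the ROI is
re-centred once on the intensity-weighted centroid — a single-pass update,
no iteration. If the clipped weights sum to zero the tracker raises a
tracking-lost error carrying the frame index. The path is clipped so the
block never leaves the image.

**Decile background.** With N ROI pixels, k = max(1, floor(0.10·N)) and the
background estimate is the mean of the k faintest pixels. The default
("scaled") mode subtracts that estimate over the full ROI area,
F = ΣROI − N·bg, which removes a uniform background completely and makes F
exactly invariant to adding a constant to every pixel. A "literal" mode
that subtracts only the decile's own sum (F = ΣROI − k·bg) is available
behind a configuration switch for comparability with analyses that read
the rule that way; it removes only a tenth of a uniform background and is
not the default. F is reported as computed and may be negative in
pathological frames; it is never clipped.

**Ratio and percent change.** Per frame, R = (F_yellow,raw −
α·F_cyan)/F_cyan with α the donor→acceptor bleed-through fraction (default
0; the correction model is one-directional linear mixing — no instrument
calibration is attempted). R0 is the mean R over the first
round(baseline_window · frame_rate) frames (default 3 s, so exactly 30
frames at 10 Hz; `round()` handles non-integer products and is documented
here as the tie-break). Frames with F_cyan ≤ 0 outside the baseline yield
NaN ratios that propagate as missing values; F_cyan ≤ 0 inside the
baseline, or R0 ≤ 0, abort with a baseline error because no meaningful
percent change exists.

**Response call.** σ_base is the sample SD (ddof = 1) of ΔR/R0 over the
baseline frames. The response window is [onset, onset + stimulus duration +
10 s], with the stimulus duration fixed by kind (press 1.0 s, buzz 3.7 s);
a window that overruns the recording is clipped with a warning. A trial is
a responder when the peak ΔR/R0 in the window exceeds
max(3·σ_base, 5%). Both constants are exposed in configuration and echoed
in every `ResponseCall`, because the original visual scoring criterion for
"responding" is not formalized anywhere we could anchor to; this threshold
is a documented operational stand-in, not a reconstruction. With ~1%
baseline noise the 5% floor dominates and is ≈ 5 σ, which keeps the
false-positive rate over a ~150-frame window negligible while a 10%
transient still clears the floor comfortably.

## Behavior scoring

**Bends.** A "C-shaped bend" is operationalized on the signed midbody bend
angle: an event fires when |angle| crosses above θ_c = 45° on the side
opposite the previous event, and the angle must fall below θ_c − 10°
(hysteresis) before the next event can fire. The 45°/10° pair is a
configuration choice — the assay is classically scored by eye — and both
constants are exposed. Hysteresis suppresses noise chatter: zero-mean noise
with SD below about a third of the hysteresis changes event counts by less
than 2%. Counting is reliable when a full cycle spans at least ~8 samples;
at coarser sampling the re-arming dip between opposite bends can be missed.

**SWIP.** Paralysis at the assay time (default 600 s) means zero bend
events in the preceding quiet window (default 5 s). The scoring window and
the bend thresholds are the only free parameters.

**Thrash frequency.** One thrash = one full left-right cycle = two
alternating bend events, the prevailing convention for swim assays (counts
can be doubled for a half-cycle convention). Frequency = events /
(2 · interval length) over a default 11-minute window, returned together
with the raw event count.

**Reversals.** A tap-evoked reversal is signed speed below
−0.05 body-lengths/s sustained for ≥ 0.2 s within 1 s of the tap; latency
is the onset of the first qualifying run. These constants stand in for a
tracker's internal criterion and are configuration-exposed. Any untracked
gap (NaN speed) overlapping the window yields an explicit *untracked*
outcome rather than "no reversal", because population denominators are
"worms tracked", not "worms on the plate".

## Population statistics

**Proportions.** Binomial CIs are Wilson score intervals by default
(well-behaved at proportions near 0 and 1, which habituated levels and
SWIP fractions actually reach); Clopper–Pearson is available by flag and
the method label is recorded in every result. Boundary intervals (k = 0 or
k = n) are snapped to exact 0/1 endpoints.

**Habituation curves and QC.** Per-tap proportions use tracked worms only,
in both numerator and denominator; a tap with zero tracked worms is kept as
a flagged gap, never interpolated. A day passes quality control when the
reference strain's tap-1 reversal proportion is at least 0.80, boundary
inclusive.

**Strain comparison.** The habituated level (reversal at tap 30 exactly,
not an average of late taps) or any other binary endpoint is modelled by a
worm-level binomial logistic regression on the strain factor (treatment
coding, first strain alphabetically as reference). All S(S−1)/2 pairwise
log-odds contrasts get Wald z statistics; the familywise adjustment is
single-step on the joint normal distribution of the contrasts (the
standard realization of Tukey-type contrasts for generalized linear
models). Because per-strain estimates are independent in this one-way
layout, the joint distribution is generated exactly by sampling the
per-strain Gaussians and propagating them through the contrasts; the
adjusted p-value p_i = P(max_j |Z_j| ≥ |z_i|) is evaluated by seeded
quasi-Monte-Carlo with 200,000 draws under a fixed internal seed, making
results reproducible to the last digit. (For S ≥ 3 the contrast
correlation matrix is singular by construction — pairwise contrasts are
linearly dependent — which rules out naive CDF evaluation but not
sampling.) Adjusted p-values are floored at the raw p-values. Bonferroni
is the fallback if the reference distribution cannot be evaluated.

**Separation.** A strain at 0% or 100% at the endpoint makes the ML fit
diverge. The model here is a saturated one-way layout, for which Firth's
penalized likelihood reduces exactly to adding 1/2 to each success and
failure cell (Jeffreys prior), so the penalized fit uses that closed form:
log-odds log((k+½)/(n−k+½)) with variance 1/(k+½) + 1/(n−k+½). Results are
flagged `penalized` rather than silently switching.

**Basal slowing.** Slowing index = 1 − mean(bends on food)/mean(bends off
food) per strain, with worm-level bootstrap intervals (seeded, 1000
resamples) and pairwise index differences. A zero off-food mean makes the
index undefined and is an error.

**Calibration.** At the conditions of the simulated study (three identical
strains, 100 worms each, 30 taps at 10 s ISI, no dropout so the endpoint
denominator equals the stated n), the familywise type-I error of the
adjusted comparison measures ≈ 0.04–0.06 at nominal 0.05 over 1000
replicates, and power for asymptotic levels 0.45 vs 0.25 at n = 100/strain
exceeds 0.8. Both are recomputed by the test suite and the acceptance
script, never quoted from elsewhere.

## Synthetic data: what it emulates, and what it does not

All randomness derives from one user seed: the stream for label L is
`SeedSequence([seed, crc32(L)])`, so streams are independent, reproducible,
and stable under the addition of new streams. Identical seeds give
bit-identical outputs, and the end-to-end pipeline is byte-identical across
runs — the determinism the provenance manifest relies on.

**Tap experiments.** Per-worm reversals are independent Bernoulli draws
with p_t = p∞ + (p0 − p∞)e^{−λ(t−1)}; tracking dropout is independent
Bernoulli per (worm, tap). Real trackers lose worms in bursts (collisions,
edge exits) and real worms differ in responsiveness; neither worm-level
heterogeneity nor autocorrelated dropout is modelled. Passing tests
therefore validate the estimators under the stated sampling model, not
robustness to overdispersion — which is why a plate-cluster robust-variance
extension remains on the roadmap rather than being silently implied.

**Image stacks.** The cell is a 2-D Gaussian spot (σ = cell_radius, default
3 px) whose transient multiplies the true YFP/CFP ratio by
(1 + ΔR/R0(t)/100); the time course is a double exponential (rise 0.5 s,
decay 3 s — typical published kinetics for genetically encoded calcium
indicators; the assays this emulates report waveforms only graphically, so
these are placeholders, not fits). The acceptor channel receives
α_true·(donor signal) as bleed-through plus a flat background; pixel noise
is Poisson on the photon mean plus Gaussian read noise. Default photon
budgets (donor peak 1000, acceptor 1250 photons/pixel, background 10, read
noise 2) put the end-to-end ΔR/R0 noise near 1% SD, the regime a bright
cameleon cell body on an EM-CCD delivers and the one the response threshold
is designed around. Not emulated: non-Gaussian cell shape, focus drift,
photobleaching, motion blur, or saturation. The generator refuses paths
that bring the cell within 3σ of the image edge.

**Swim traces.** Bend angle = amplitude·sin(2πft) plus Gaussian
measurement noise; at a paralysis onset the sinusoid's amplitude ramps
linearly to zero over 2 s (no real worm stops discontinuously) while the
measurement noise persists. Paralysis onsets in simulated SWIP assays are
drawn well before the 10-minute mark (uniform on [120, 500] s in the
pipeline, [100, 590] s in the validation studies), reflecting the gradual
accumulation of paralysis in the real assay; onsets inside the quiet
window itself would make ground truth ill-defined at the boundary.
A sampling rate below the Nyquist limit for the thrash frequency is
rejected outright.

## Numerical conventions and degenerate inputs

- Baseline frame count uses `round()`; the decile size uses `floor` so the
  background sample never reaches median-brightness pixels; ROI area must
  be ≥ 10 px so the faintest decile is non-empty.
- Division guards: R is NaN where F_cyan ≤ 0, never zero-filled.
- Zero-crossing bookkeeping: a sinusoid of frequency f over duration T has
  2fT zeros on the half-open interval; when the final zero lands exactly on
  the last sample a finite trace realizes one fewer interior sign change.
  The generator tests account for this boundary effect explicitly.
- CSV output uses `%.10g` floats, UTF-8, comma separation, header rows,
  and empty fields for missing values; TIFF stacks are frame-major with
  the CFP page preceding the YFP page per time point and the layout
  recorded in the image description as JSON.

## Problem sizes used in validation

The shipped validation runs use: 1000 random ROIs for the background
oracle; 50 stacks of 64×64 px × 300 frames (40 with transients of 10–50%,
10 without) for end-to-end recovery; 100 frames of 0.5 px/frame drift for
tracking; 200 simulated swim traces for SWIP rule fidelity and 100 for
thrash accuracy; 1000 null and 500 alternative replicates for calibration
and power; and 10,000 draws for Wilson coverage. These sizes give the
quoted properties comfortable Monte-Carlo margins while keeping a full
validation run around a minute on a single CPU.

## Known limitations

- The responder threshold and the reversal/bend constants are operational
  stand-ins for criteria that were never formalized upstream; conclusions
  that hinge on their exact values should sweep them via configuration.
- The logistic comparison treats worms as independent; day and plate
  effects are not modelled (a cluster-robust variance option is the
  natural extension).
- Bleed-through correction is linear and one-directional with a
  user-supplied coefficient; no spectral calibration is performed.
- The ROI tracker handles slow drift, not jumps: a displacement larger
  than the ROI between consecutive frames loses the cell.
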