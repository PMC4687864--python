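# Methods

`wheelgait` reconstructs single-limb vertical ground-reaction forces (GRF)
from a force-sensing rodent exercise wheel, extracts gait kinematics, and
places each running bout on a continuous gait-symmetry scale (3S).  Because
no instrument data ship with the package, a physics-based simulator with
full ground truth stands in for the wheel; every processing stage is
validated against it.

## The instrument model

The simulated wheel mirrors the physical design: 16 sprung pads in 4 groups
of 4, each pad carrying a magnet, rotating over a fixed arc of 9 Hall
sensors sampled in parallel at 3 kHz.  One revolution corresponds to 0.25 m
of running path, so 1 revolution/s = 0.25 m/s.  Key sensor parameters
(defaults): baseline 2.5 V, gain 2 V/N, Gaussian noise with sigma =
0.0133 V (3-sigma band ~0.04 V, the instrument noise threshold), baseline
drift 0.63 mV/h, recording trigger at a 0.2 V departure from baseline.

Magnet-sensor coupling is a smooth raised cosine in angular offset reaching
zero at one pad pitch.  Adjacent responses tile to exactly one
(cos^2 + sin^2), so a uniformly loaded wheel reads its true total force —
the regime in which the mean-voltage calibration protocol operates — and
the per-sensor calibration lines recover the configured gain.  The support
struts between pad groups carry no magnet; when a strut gap crosses a
sensor, the reading blends to a magnet-free floor (0.5 V below baseline)
regardless of limb forces.  These dips pass the central sensor four times
per revolution and drive wheel-speed estimation; they also transiently
corrupt force readings whenever they cross the sensor that happens to be
reading the loaded pad, an artifact discussed below.

## The virtual mouse

A mouse (default mass 34 g, hip height 2.6 cm) runs in place while the
wheel turns beneath it.  Each limb exerts a half-sine vertical force during
its stance; peak forces come from impulse balance so each limb pair
supports its share of body weight:

    F_peak(limb) = pi * beta_pair * m * g / (4 * DF)

with a fore:hind weight split of 0.51:0.49 and per-limb duty factor DF.
An optional lateral bias (left limb's share of its pair, default 0.5)
models limb dominance.  A foot lands on whichever pad is under its
station at touch-down and rides that pad across the sensor arc.  The hind
feet sit nearly side by side and land on one pad when they touch down
together (the half-bound signature: a summed double-force peak); the fore
feet are laterally offset and land on distinct pads.

Gait timing uses idealized Hildebrand phase patterns for creep, trot,
gallop and half-bound, anchored at first hind contact.  The cohort
generator perturbs them the way real strides deviate:

* trot — the second diagonal step lands early by 2–6% of the stride
  (left-right unevenness), which is what puts a stride-rate line into the
  force spectrum; a perfectly symmetric trot's trace has a half-stride
  period and its stride frequency is unrecoverable *in principle*;
* creep — "fairly intermittent" exploratory walking: the stride clock
  pauses before a stride with probability 0.35, by up to 0.4 stride;
* all gaits — small white phase jitter (sd 0.008 stride) and a per-trial
  lateral bias drawn from 0.52–0.55.

Speeds are drawn per gait from truncated normals reflecting observed
wheel-running structure (overall preferred speed ~0.50 ± 0.13 m/s): creeps
below the walk-trot transition band (whose Froude-predicted lower edge is
0.36 m/s for a 2.6 cm hip), trots centered at 0.52 m/s, bounding/galloping
centered at 0.72 m/s with duty factors capped at 0.35 (aerial-phase
gaits).  Stride frequency follows 3.2 + 5.4 v Hz and duty factor
0.8 − 0.55 v (v in m/s), linear trends through reported mouse kinematics;
fore stances are 10% shorter than hind (split 0.9 : 1.1 about the mean).
Trials last a whole number of strides (default 16), as steady bouts do,
which also keeps spectral lines on FFT bin centers.

## Reconstruction chain

1. **Trigger** — intervals open when the central sensor departs ±0.2 V
   from a rolling 1-s median baseline, close after 1.5 s of quiet, and are
   chunked into ≤5 s blocks.
2. **Calibration** — per-sensor least-squares lines of mean voltage
   against applied force from the rotating-mass protocol (masses 1–41 g);
   slopes in V/N with R² recorded per sensor.
3. **Speed** — strut minima on the central channel (local minima ≥0.1 V
   below the unloaded baseline, prominence ≥0.25 V); between consecutive
   minima, omega = f/(4 s) revolutions/s with f the sample rate and s the
   sample gap.  The unloaded baseline is the 10th percentile of the
   window: limb forces only raise the voltage, struts only lower it.
4. **Maximum concatenation** — per sample, the largest calibrated force
   across sensors, negatives floored at zero.  Two feet on one pad appear
   summed; on different pads only the larger force enters the trace.
5. **Spline smoothing** — a natural cubic spline through one knot per
   constant-winning-sensor segment (the argmax index is median-filtered
   over 15 samples first, since near-ties flicker).  In loaded segments
   the knot sits at the segment's maximal sample, where sensor response
   is best aligned and closest to the true force; segments below a noise
   floor (5x the sample-to-sample noise scale) anchor at their median, so
   swing phases do not ride on noise maxima.  Output is clipped at zero.
6. **Two-peak spectral filter** — the two largest non-DC rFFT magnitude
   bins are kept (ties: lower frequency), everything else zeroed, and the
   retained non-DC coefficients scaled by a common factor so output energy
   equals input energy (Parseval); DC is retained unscaled so mean force
   stays meaningful (`zero_dc=True` drops it).  A "peak" is a single bin;
   bin leakage on short windows is the main fidelity limit.

In this simulator the raised-cosine response keeps the raw maximum trace
within a few percent RMS of the true limb force, so the spline's practical
value is suppressing the sensor-handoff ripple (at the sensor-passage
frequency, 2 pi rps / sensor pitch) rather than reducing pointwise RMS
error; the test suite asserts ripple-band energy reduction and bounded
fidelity accordingly.

## Kinematics

Stride boundaries come from the filtered trace: the fundamental is the
approximate greatest common divisor of its two spectral lines, with a
subharmonic check (a bin at half the fundamental carrying ≥2% of the
dominant bin's power halves it) for uneven trots.  Stances are measured on
the *splined* trace — the two-bin filter reshapes pulse widths — as
contiguous runs above max(5% of stride peak, 0.025 N), segmented once over
the whole record and assigned to 3-stride blocks by midpoint so no stance
is split at a window edge.  Runs shorter than 10 ms or below 10% of the
trace maximum are noise, not contacts.  Blocks whose speed varies by more
than 1 revolution/s (0.25 m/s) are discarded.  Only single-peak stances
enter stance statistics, with the peak count taken from the ripple-robust
footfall detector (below): at running duty factors the contact chain of a
half-bound has a single aerial gap per stride, so merged multi-limb runs
are excluded and duty-factor coverage is partial there — the same
exclusion the manual protocol applies.  Where coverage exists, recovered
duty factors land within ~0.02 of the matched limbs' true values.

Peak limb force is predicted from the same half-sine model,
F = c·beta·m·g/DF with c = pi/4 by default (per-limb impulse balance);
the constant is exposed because per-pair conventions use pi/2.

Fore/hind impulses are measured on the splined trace from fast half-bound
bouts (~0.95 m/s, duty ~0.28), where aerial gaps separate the hind-pair
pulse from the two fore pulses — the regime in which fore and hind signals
are distinguishable.  Each footfall's impulse is the trapezoid integral of
the contiguous region above 5% of its own peak between flanking valleys
(a relative threshold trims all pulses by the same fraction, leaving the
ratio unbiased); footfalls are attributed by a two-means split on peak
height, the hind-pair cluster sitting near twice a fore peak.  With the
0.51:0.49 split the construction ratio is 0.49/0.51 = 0.961; the pipeline
reads back ~0.97–0.98.  At lower speeds pulse overlap biases the ratio
high, and above ~1 m/s the narrow hind pulse is under-resolved by the
spline — both limits of the max-concatenated signal, not of the animals.

## The 3S metric

Footfall (peak) times are detected on the splined trace with a height
threshold of 10% of the trace maximum, a prominence threshold of the same
size, a minimum separation of 0.15 of the trace's dominant period, and an
anti-ripple guard band: a zero-phase low-pass whose cut sits just below
the sensor-passage frequency, clipped to between 3x and 7x the dominant
spectral line (3x is the resolution floor for a 0.2-stride footfall lag).
Peak positions are refined to sub-sample precision by parabolic
interpolation — at 3 kHz, raw quantization would inject white jitter into
the twice-differenced interval wave.

The score: successive inter-peak intervals d are differenced twice to a
wave u; the peaks-per-stride period P (2–4) is read off a periodogram of
d; u is trimmed to whole periods (a trailing partial period breaks the
circular pairing and deflates even a perfect trot); and

    3S = MSE(u, circular-shift(u, round(P/2))) / (4 * mean(u^2)),

clipped to [0, 1].  A trot's alternating intervals make u exactly
antisymmetric under a half-stride shift (score 1); a half-bound's
three-interval sawtooth scores 3/4 (an algebraic identity for any circular
period-3 pattern — the metric orders gaits but ideal k-peak patterns take
discrete values); a perfectly even train scores 1 by convention.  Because
the score is a mean-square statistic, one missed or split peak can
dominate a long trace, so trace-level scores are the median over
overlapping 9-peak windows.

Two structural caveats, verified analytically: (i) any gait whose trace
shows only two peaks per stride produces alternating intervals and scores
trot-like — the discrimination lives entirely in whether the asymmetric
gait's third footfall is resolved; (ii) the second difference of an
isolated timing irregularity is the [1, −2, 1] kernel, which is itself
antisymmetric at lag 1, so white timing jitter biases scores toward ~0.83
at P = 2 rather than toward 0.  Merged-couplet creeping traces therefore
cannot score low through an interval-only metric; creeps are instead given
their observed intermittency in the generator and carry an asymmetric
label (their pair footfalls are not evenly spaced in time).

The symmetric/asymmetric threshold is calibrated per dataset by sweeping
midpoints of sorted unique scores and locating the intersection of the
specificity curve (fraction of symmetric gaits called symmetric) and the
sensitivity curve (fraction of asymmetric gaits called not-symmetric);
among candidates within 0.02 of the minimal curve gap the most accurate is
returned, since with discrete scores the crossing falls between
candidates.  The calibration depends only on score ranks.  On mixed
trot/half-bound/gallop cohorts of 240 trials at instrument noise, the
held-out half classifies at 95–98% across seeds, with thresholds around
0.75–0.84 on this normalization (threshold values are not portable across
3S normalizations, which is why recalibration is part of the method).

## What the simulator does and does not establish

Passing tests show the chain recovers what this instrument model encodes:
wheel speed (exact to <0.1%), stride frequency (100% of blocks within 5%
at 0.3–1.0 m/s), duty factor where single-limb stances exist (>=90% of
reporting blocks within 0.05), the fore:hind impulse split, and the
trot-versus-bounding symmetry ordering.  The generator does not emulate:
variable within-bout speed profiles beyond piecewise-linear, tangential
forces, pad vibration ringing, foot-position-dependent sensitivity (off
by default), multiple animals, or coasting.  Low-speed grounded gaits
(duty >0.5) have no force-trace zero crossings, so their stance periods
are unrecoverable by design — the real instrument shares this limit.
Strut-gap transits corrupt a few milliseconds of force reading per
revolution; the windowed-median score contains, but does not remove, the
resulting occasional peak-time glitch.

## Reproducibility

All randomness flows from explicit seeds; `generate_trial` is bit-exact
across runs for a fixed seed, and with zero noise and drift it is exact
across platforms up to floating-point determinism of the underlying BLAS.
Problem sizes used by the acceptance script: a 60-trial parameter-recovery
cohort, a 240-trial classification cohort, 100 random traces for the
energy-preservation check, and 8 half-bound bouts for the impulse ratio.
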