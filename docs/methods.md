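# Methods notes

This note documents the models, defaults and numerical choices behind
`flytread`, and what the test suite does and does not demonstrate.

## Display geometry

The projection assumes a point viewer on the axis of a virtual cylinder,
looking perpendicular to a flat panel: azimuth θ maps to screen offset
x = d·tan θ with d = 35 mm.  Elevation uses the same tangent formula on the
vertical axis; no cylindrical curvature is applied in elevation, since the
virtual cylinder's height exceeds the rendered frame and no vertical warp is
defined.  Angles are degrees at every interface and radians internally.

The panel's physical dimensions are not uniquely determined by the published
viewing spans; we fix them once at 151.8 × 83.4 mm (1024 × 600 px, a typical
7-inch tablet) because that choice reproduces the ~130° azimuth / ~100°
elevation coverage at 35 mm.  Pixel pitch is assumed constant.

Sign convention: azimuth 0° is straight ahead, positive to the fly's right;
positive ω ("clockwise", CW) moves the pattern toward positive azimuth.  With
the spatial axis plotted right-to-left and time downward, CW motion tilts
down-and-left in space-time diagrams.

The virtual cylinder diameter (default 305 mm, the scale of a typical LED
arena) is deliberately cosmetic: for an on-axis viewer only angles matter, and
a test asserts diameter-invariance of the rendered image.

## Stimuli and protocols

Gratings are ideal square waves (half period bright, half dark), sampled at
pixel-column centers with no anti-aliasing — appropriate for a high-contrast
LCD stimulus; an optional supersampling factor exists for sensor-averaging
experiments.  The initial grating phase defaults to 0 (a bright bar starting
at azimuth 0); no convention is published, and none of the analyses depend on
it.

Bar sweeps default to a travel span of 175.5° = visible azimuth span (130.5°)
+ bar width (45°), so the bar starts fully off one screen edge and ends fully
off the other.  This choice exactly reproduces the published 0.13–7.8 s
per-trial duration range for the six standard speeds.  During bar pre/post
epochs the screen is uniformly dark rather than showing a frozen bar.

Block randomization draws each block as an independent uniform permutation
from a single named generator (`numpy.random.default_rng`) seeded from the
protocol; no global random state is touched anywhere in the package.  One
closed-loop trial is appended after each block by default — the published
cadence of interleaving is unspecified, so this is configurable and can be
disabled.

## Trial engine

Server and client share one simulated clock (integer microseconds, exported
in ms).  Real setups have two clocks synchronized over the network; modeling
clock skew is out of scope, and the single-clock simplification is a
simulation choice, not a claim about how real systems reconcile timestamps.

"On time" means a frame completed within one nominal inter-frame interval
(1000/60 ≈ 16.7 ms) of its schedule.  Transport latency (a fixed floor plus
exponential jitter, delivered in order) only delays *parameter application*;
frame drops are injected separately through a render-timeout model
(deterministic every-nth frame and/or Bernoulli), because in the real system
dropped frames come from the browser's render loop, not from the network.  A
delayed frame re-shows the content that was current one deadline earlier, so
no frame can ever display parameters newer than the latest delivery.

The default transport (1 ms floor + 2.5 ms exponential jitter one-way) was
chosen once as a realistic local-Wi-Fi scale; with it, ~98 % of simulated
round-trips complete within one 60 Hz frame interval.  A real network service
behind the same transport interface would be a straightforward extension; all
tests run in-process.

## FicTrac format

Files are comma-delimited 25-column numeric text; `#` comment lines are
skipped, and writing uses `%.17g` so write∘read is exact.  Column indices
(heading = 17, movement speed = 19, delta timestamp = 24, 1-based) follow the
published FicTrac data-file layout and are configurable through a format
descriptor.  "Animal movement speed" is interpreted as radians of sphere
rotation per camera frame — the only reading under which dividing by the
delta timestamp and multiplying by the 4.5 mm sphere radius yields a walking
speed in mm/s; the assumption is isolated in the format descriptor and
documented here.

## Synthetic fly

The generator emulates the study conditions: forward speed 10 ± 2 mm/s
(Gaussian per camera frame, clipped at 0), camera rate 180 Hz, turning gain
peaking at 50 °/s at 4 Hz with log-Gaussian width 1.5 (ln units), sensory
latency 50 ms, and white motor noise of 25 °/s SD on the yaw velocity.

Three modeling choices were genuinely open:

* **TF tuning form.**  A log-Gaussian is the minimal unimodal tuning
  consistent with the qualitative physiology; the analysis pipeline never
  assumes this form — it only computes empirical means.
* **Rendered-stimulus coupling.**  The drive direction comes from the sign of
  the net-motion index of the *rendered* space-time diagram (cached per
  condition), not from the nominal ω.  This makes the aliased
  TF-=-half-refresh condition drive exactly zero mean turning, reproducing the
  control logic of the display.  Spatial acuity enters as Gaussian ommatidial
  blur with a 5° acceptance angle applied to the grating fundamental —
  attenuation exp(−(πΔρ/λ)²/(4 ln 2)) — so λ = 5° gratings evoke ~3 % of the
  λ = 90° response, qualitatively matching real flies.
* **Bar drive.**  Bars have no published tuning variable; the drive uses the
  TF of a grating whose bars match the bar width (|ω|/(2·45°)) and is gated to
  the interval when the bar overlaps the visible field.  A midline-gating flag
  (respond only to progressive motion, after the bar crosses azimuth 0) is
  available but off by default because no functional form for the position
  dependence is established.

Closed-loop trials get zero mean drive in the open-loop simulator; the engine
still applies the fly's (noise-driven) turning to the logged stimulus
orientation through the coupling gain, and a coupled fixed-point test covers
the gain = −1 stabilization algebra separately.

## Analysis

Smoothing is a centered 5-camera-frame moving average (~28 ms at 180 Hz)
applied to the continuous per-fly yaw series *before* trial slicing and
averaging; at the series edges the window truncates symmetrically.  Whether
smoothing precedes or follows trial pooling is ambiguous in conventional
descriptions; smoothing-first is used and fixed here.

The stimulus epoch is half-open [motion onset, offset).  Trials are aligned by
event-log timestamps, not FicTrac frame counters, because display (60 Hz) and
camera (~180 Hz) run at different rates.  Per-trial traces are binned onto a
camera-rate grid relative to motion onset.  SEM is computed across flies
(sd/√n_flies), matching the per-fly-first averaging; with fewer than two
flies the SEM is reported as NaN.

## What the tests show — and don't

Passing tests demonstrate internal consistency and exact implementation of
the stated conventions: projection closed forms agree with per-pixel ray
casting, frame accounting is exact under constructed delay injections, the
analysis is antisymmetric under heading negation and immune to turning bias,
and the full pipeline recovers the injected tuning optimum (4 Hz) and the
zero response at the 30 Hz control from 30 simulated flies × 6 blocks × 14
conditions.  They do **not** show anything about real animals: the synthetic
fly has no biomechanics, no state dependence, no spontaneous saccades, and
its noise is white, so real-data effect sizes, trial-to-trial correlations
and outlier structure are all out of model.  Likewise the simulated
photodiode has no sensor noise (deliberately — the 60 Hz ripple seen on real
sensors is a measurement artifact), and no display brightness/gamma
non-uniformity is modeled.

## Problem sizes and tolerances

The parameter-recovery suite runs the full study scale (30 flies, 6 blocks,
14 conditions; ~67 k camera frames and ~22 k display frames per fly) — about
15 s on one CPU thanks to vectorized simulation.  Smaller unit fixtures use
1–3 flies and 1–2 blocks.  Exact assertions are used wherever the quantity is
exact by construction (counting, round-trips, algebraic identities);
stochastic assertions use 3–4 standard errors; printed-value checks use the
precision of the printed figure.
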