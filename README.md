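# flytread

A headless, fully testable re-implementation of a spherical-treadmill
("fly-on-ball") visual experiment stack for walking *Drosophila*.  A tethered
fly walks on an air-supported foam sphere facing a flat tablet display; the
display shows moving gratings and bars whose on-screen widths are corrected
for viewing angle, the sphere's rotation is recorded in FicTrac's 25-column
file format, and the analysis reduces the recordings to optomotor tuning
curves.  Everything — display, network transport, camera, and the fly itself —
is simulated, so the complete stimulus → behavior → analysis chain can be
developed, validated and taught without hardware or animals.

It is intended for behavioral neuroscientists and instrumentation developers
who build or analyze tethered-insect virtual-reality experiments.

## The models at the core

**View-angle correction.** A fly sits a distance *d* = 35 mm from a flat
panel.  To emulate a cylindrical display, an azimuth angle θ maps to the
physical screen offset *x* = *d*·tan θ, so equal visual angles get physically
wider toward the screen edges (a 10° bar near the edge is ~3× as wide on
screen as one at the center).  The default 151.8 × 83.4 mm panel at 35 mm
subtends ~130° of azimuth and ~100° of elevation.

**Stimuli and protocols.** Square-wave gratings of spatial period λ move at
angular velocity ω, giving temporal frequency TF = |ω|/λ.  The standard
protocols are: temporal-frequency tuning (λ = 90°, TF ∈ {0.25, 1, 2, 4, 7.5,
15, 30} Hz, both directions — 14 conditions), spatial-period tuning
(λ ∈ {5 … 120}° at TF = 7.5 Hz — 14 conditions), and single 45° bright-bar
sweeps at six speeds per direction (durations 0.13–7.8 s).  Each trial is
500 ms static, 3 s motion (bars: one sweep), 500 ms static; conditions are
presented in 6 randomly ordered blocks after a 10 s startup delay.  The 30 Hz
condition is a built-in control: at half the 60 Hz display refresh the
grating advances λ/2 per frame, which is pure flicker and carries no net
motion.

**Trial engine.** A simulated server announces scene parameters at epoch
boundaries; a simulated client renders a frame every refresh using the latest
delivered parameters, re-showing the previous content when an update misses
the frame deadline.  Transport latency (fixed floor + exponential jitter) and
render timeouts are injectable, and everything is logged as time-stamped
key–value entries plus per-frame render records, enabling exact on-time-frame
and round-trip-latency accounting.

**Treadmill conversion.** From FicTrac records, yaw velocity is the unwrapped,
first-differenced heading divided by the per-frame delta timestamp; walking
speed is sphere rotation (rad/frame) × sphere radius (4.5 mm) / Δt.

**Analysis.** Yaw traces are smoothed with a 5-camera-frame sliding window,
averaged per fly within each condition, counterclockwise responses are scaled
by −1 and averaged with clockwise ones (cancelling direction-independent
bias), and tuning curves report mean ± SEM across flies of the mean turning
velocity during stimulus presentation.

**Synthetic fly.** The simulated animal walks forward at ~10 mm/s (camera rate
180 Hz) and turns with the stimulus at a log-Gaussian TF-tuned gain (peak
50 °/s at 4 Hz by default), driven by the *rendered* stimulus — so the aliased
30 Hz control correctly evokes no turning — and attenuated by ~5° ommatidial
blur, so λ ≤ 10° gratings evoke little response.

## Worked example

```python
from flytread import DisplayGeometry, TransportModel, run_experiment
from flytread.stimuli import build_protocol, randomize_blocks
from flytread.simfly import FlyModel
from flytread.analysis import analyze_tuning

geom = DisplayGeometry()                       # 1024x600 px, 35 mm, 60 Hz
proto = build_protocol("temporal", n_blocks=6)
runs = []
for i in range(5):                             # five synthetic flies
    trials = randomize_blocks(proto, seed=100 + i)
    runs.append(run_experiment(trials, geom,
                               TransportModel(1.0, 2.5, seed=300 + i),
                               FlyModel(seed=200 + i)))
res = analyze_tuning(runs, label="temporal frequency (Hz)")
print(res.tuning.to_frame().to_string(index=False))
```

prints

```
    x  mean_dps  sem_dps  n_flies
 0.25  8.763856 0.148883        5
 1.00 31.582037 0.104768        5
 2.00 43.819194 0.098045        5
 4.00 48.543271 0.183135        5
 7.50 44.599123 0.093616        5
15.00 32.981317 0.195768        5
30.00  0.058594 0.086900        5
```

Each row is one temporal frequency: the combined (CW − CCW)/2 turning
velocity during the motion epoch, mean ± SEM across the five flies.  The
curve peaks at the injected 4 Hz optimum and collapses to ~0 at the 30 Hz
flicker control, exactly as the display physics dictates.  The same result
object reports the mean forward walking speed (~10 mm/s) and the number of
interleaved closed-loop trials excluded from tuning (here 30: one per block
per fly).

A command-line interface wraps the same pipeline:

```sh
flytread simulate --protocol temporal --flies 5 --seed 1 --out out/
flytread analyze --data out/ --out analysis/
flytread render-spacetime --condition grating-tf7.5-cw --out diagram.png
flytread validate
```

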