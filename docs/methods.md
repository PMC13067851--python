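# Methods

This note documents the models, parameters and design choices behind
`optoloop`, in the order data flows through the closed loop.

## Tissue model

The monolayer is a square grid of excitable nodes with a centered conducting
disc; everything outside the disc is inert, and coupling weights across the
disc boundary are exactly zero (a zero-flux Neumann condition, so total
membrane variable is conserved when the reaction is switched off).  Node
centers sit at `(i + 0.5) * spacing`, row-major; the reference geometry is a
15 mm disc inside a 15.36 mm field.

Each node carries a two-variable phenomenological excitable model of the
Aliev–Panfilov form,

    du/dt = [ -k u (u - a)(u - 1) - u v ] * s / tau + I_stim + I_photo
    dv/dt = [ (eps0 + mu1 v / (u + mu2)) (-v - k u (u - a - 1)) ] / tau

with `u` the normalized membrane variable (`V = -80 + 100 u` mV) and `v` the
recovery variable.  Defaults: `k = 8`, `a = 0.08`, `eps0 = 0.002`,
`mu1 = 0.2`, `mu2 = 0.3`.  The time scale `tau = 2.2 ms` and diffusivity
`D = 0.008 mm^2/ms` were calibrated once, on a fine (256^2, 60 µm) grid, to
monolayer-like electrophysiology: APD80 ≈ 104 ms, plane-wave CV ≈ 100 mm/s,
spiral frequency ≈ 15–17 Hz, wavelength ≈ 10 mm — small enough for a 15 mm
well to sustain reentry.  A pluggable cell-model factory leaves a slot for
detailed ionic models; everything in this package uses the phenomenological
model.

Integration is explicit forward Euler for the reaction and an explicit
5-point Laplacian for diffusion, one shared time step.  The reference step is
0.005 ms (250 000 steps for a 1.25 s recording, one frame per 1200 steps →
208 frames at 6 ms).  The phenomenological model is stable at much coarser
steps; desk-scale runs use 0.1 ms on a 64^2 grid (0.05 ms at 128^2), with an
explicit stability guard `4 D s dt / h^2 < 1` that raises on violation.
Divergence (non-finite or runaway state) raises an error naming the step.

### Heterogeneity

Three multipliers emulate sample-to-sample and cell-to-cell variability:

- global ionic-current scale, uniform on [0.83, 1.20];
- per-node scale, log-uniform on [0.5, 2.0] times the global value (median
  exactly the global value);
- coupling scale, log-uniform on [0.25, 4].

The coupling draw is log-uniform rather than uniform because it is a
symmetric multiplicative factor (¼× to 4×): a uniform draw would put half the
probability mass above 2×, where CV × APD exceeds the 15 mm disc and almost
no sample can sustain reentry.  With the log-uniform draw roughly half to a
quarter of samples fail to sustain a spiral, which is the regime the
synthetic-data pipeline is designed around.  The ionic multipliers scale the
`du/dt` reaction term (the membrane currents); recovery kinetics are left
unscaled.

### Photocurrent

Blue-light depolarization is an instantaneous conductance
`I_photo = g * irr * (u_rev - u)` with `g = 1.2 /ms` at full normalized
irradiance and `u_rev = 0.85` (≈ +5 mV), i.e. no channel kinetics.  This
reproduces the three phenomena the loop needs: optical pacing (a 50 ms spot
launches a wave from the illuminated nodes), intensity-dependent conduction
block (a sustained line blocks an incoming wave at irradiance ≳ 0.03 and
passes it at ≲ 0.01), and line-mediated reentry termination.  Note that
switching a sustained line on in excitable tissue first launches a wave of
its own before the line settles into a depolarized, inexcitable strip.

### S1S2 induction

S1 is a planar wave from the left edge strip; S2 is a half-plane stimulus
below a horizontal line through an anchor point P drawn uniformly from the
conducting disc.  S2 is timed to arrive just as the repolarization tail of
S1 crosses P, scheduled from the reference CV and APD with the CV estimate
scaled by sqrt(coupling) per sample — the in-silico analogue of tuning the
S1–S2 interval to each monolayer.  The premature half-wave breaks along the
recovery gradient and curls into a single spiral (always the same chirality;
the dihedral augmentation later balances it).  Failures (no propagation, no
sustained spiral, or a core that leaves the detector crop) are recorded with
their reason and excluded; at desk scale they are roughly half of draws.

## Phase singularities and ground truth

Phase is constructed per node by time-delay embedding,
`theta = atan2(V(t + tau) - Vbar, V(t) - Vbar)` with `tau = 2` frames and the
per-node temporal mean as origin (analytic-signal phase is available as an
option).  Nodes whose signal range is under 5% of the movie's global range
are flagged invalid.  A phase singularity is a 2×2 plaquette whose four
wrapped phase differences sum to ±2π (wrapping to (−π, π] makes the test
exact); it is reported at the plaquette center, giving half-integer
coordinates.  The sum of detected charges over a region equals the winding
number of the phase along its boundary — the suite checks this identity
against an independent boundary-integral oracle on random band-limited
fields.  Per-frame detections are linked by nearest-neighbor association;
the longest-lived track is the labelled core (ties go to the track farther
from the boundary).

A caveat used by the tests: when a singularity sits exactly on a node
center, its winding spreads over the four surrounding plaquettes and can be
reported as a small cluster of adjacent detections; analytic fixtures
therefore place singularities at half-integer positions.

## Training corpus

One base sample = one heterogeneity draw + one S1S2 induction + a 208-frame,
6 ms recording started after a 150 ms stabilization delay.  Movies are
rendered to the camera raster (100×100, area-weighted block averaging, which
handles the non-integer grid-to-raster ratio exactly) with seeded additive
Gaussian noise (sd 0.02 of the normalized fluorescence range).  Each sample
contributes windows at seeded random start frames — random, because fixed
starts would expose only one phase of the rotation and the detector then
fails on arbitrary-phase input — and each window is expanded by the eight
dihedral transforms (exact on the square raster; chirality flips under
mirroring).  Windows are stored after the runtime preprocessing
(pack-background subtraction, 3×3 binomial low-pass, center crop 100→86) so
the training and closed-loop input distributions match.  The target is an
isotropic Gaussian bump (σ = 3 px, peak exactly 1 at the core pixel) at the
window's last frame.  The 80/20 train/validation split is drawn at the base
sample level so augmentations never straddle the split.

Desk-scale study conditions: 56 accepted base simulations on a 64^2 grid,
one window each, ×8 augmentation → 448 windows.  Paper-scale (256^2 grid,
thousands of patterns) is reachable through `GeneratorConfig`.

What the generator does *not* emulate: dye photophysics and photobleaching,
optical point-spread, motion artifacts, excitation-light reflections,
multi-rotor episodes, and irregular monolayer shapes.  Passing tests say the
pipeline is self-consistent under the model's physics; they do not certify
performance on real optical-mapping recordings.

## Network and training

The detector maps a 5-frame 86×86 window to an 86×86 core-probability map:
per-frame central-difference spatial gradients are appended as channels
(value, gy, gx), then a 3×3×3 convolution (valid in time: 5→3; 16 channels),
3×3×3 max pooling with stride 1×2×2 (time → 1, 86→43), a 1×3×3 convolution
(32 channels), 1×3×3 pooling stride 2 (43→21), two stride-2 transposed
convolutions (21→42→84), bilinear resize to 86 and a sigmoid.  ~8100
parameters (≈32 KiB).  The stated kernel/stride/pooling shapes with standard
padding conventions do not reproduce a 39×39 intermediate under any single
convention we could construct; the implementation uses same-padding
arithmetic 86→43→21 and decodes back, which we document as a deliberate
deviation.

The loss is `mean |pred - target| + λ · max(0, ε - max(pred))` per sample.
The hinge prevents the trivial all-zero solution; defaults λ = 5, ε = 0.8
were chosen so that trained peaks clear the 0.7 decision threshold of the
control loop.  Two numerical choices matter a great deal at small training
budgets:

- the final bias is initialized at the background prior logit (−4.5).  With
  a zero bias the L1 pull drives every pre-activation far negative in the
  first epochs and the vanishing sigmoid slope silences the gradient of the
  rare core pixels (the network "dies" into the all-zero solution);
- optimization is Adam (lr 1e-3, batch 8, 20 epochs at desk scale; constant
  schedule, cosine available).

All layers (including backprop) are implemented in numpy with im2col/BLAS
convolutions; training is deterministic given the seed on one machine.

### Known limitation: desk-scale localization accuracy

At desk scale (448 windows, 20 epochs, ~900 gradient steps) the median
held-out localization error plateaus around 30–45 px, and pushing to 100
epochs or 4× the windows does not move it below ≈20 px.  Two measurements
bound what is achievable here: (i) running the phase-singularity detector
itself on single 5-frame windows finds a singularity in only ~40% of
windows (2–3 px accurate when it does), so a single 30 ms window is
intrinsically a hard input; (ii) the phase-rich task at this optimization
budget is roughly two orders of magnitude short of the full-scale training
regimen (thousands of patterns × 100 epochs) under which this architecture
is known to localize precisely.  The decision layer partially compensates by
excluding a 6 px rim of the probability map from the peak search (edge
responses are convolutional boundary artifacts) and by the 10-frame
histogram stabilization.

## Decision layer and closed loop

Packs of five raw 100×100 frames arrive at 8 ms.  The last frame of each
pack is the background for the next (first pack: zeros, treated as warm-up);
frames are blurred with the 3×3 binomial kernel and center-cropped to 86.
The detector's (argmax, peak) pairs fill a 10-deep sliding buffer; when the
buffer is full and the mean of the 10 peaks is strictly above 0.7, the
histogram's modal coordinate is the core (ties go to the most recent
occupant, favoring a drifting rotor's current position).  Detection runs
continuously; the LED output is armed only outside the settle (3 s), pulse
(0.5 s) and blanking (3 s) windows.  The light pattern is a straight line
from the core to the nearest non-conducting pixel (exhaustive Euclidean
search; distance ties broken by smallest angle from +x), 3 px wide by
default, optionally dotted at a configurable pitch, rasterized to the LED
grid so every path pixel is covered by a lit LED.  A decided core falling
outside the conducting mask (an artifact) is snapped to the nearest
conducting pixel.  Multi-well operation applies the same rule independently
per rectangular zone with per-well enables.

Termination is declared when, over a 1 s hold window, no core decision fires
AND either the high-pass amplitude stays below a quiescence threshold (0.15)
or the trigger was evaluated throughout (so residual organized activity that
the detector never localizes — a paced planar rhythm — does not count as
reentry).  Closed-loop efficacy in the test suite is scored by the physical
rotor-survival readout (fraction of tissue excited at the horizon), not by
the detector's own termination event.

With correctly placed (oracle) lines, one 0.5 s pulse terminates ~75% of
desk-scale spirals; displaced lines degrade gracefully (~25–50% at 20–40 px
displacement), which is why the loop retains substantial efficacy despite
the detector's desk-scale localization error.

## Virtual rig

The camera renders the simulator state by area-weighted block averaging to
100×100, applies gain and polarity to normalized fluorescence
(`F = (V + 80)/100`), and adds seeded Gaussian noise.  The LED matrix is
centered on the field; `box` projection lights each lit LED's pitch-sized
footprint uniformly at the pattern intensity (the `lambertian` mode uses the
physical superposition).  Registration is identity-up-to-scale; misalignment
is injected explicitly for tolerance experiments.  Heterogeneity, S2
location, camera noise and network initialization all draw from named child
streams of one master seed, so every run is replayable.

## LED layer

Patterns pack row-major, MSB first, eight LEDs per byte (byte count = pixel
count / 8).  Each emitter is a Lambertian point source: relative irradiance
`H^4 / (H^2 + d^2)^2` on a plane at distance H, normalized to the on-axis
peak, additive over emitters and linear in the intensity scale.
Illumination uniformity is min/max irradiance sampled over the central pitch
cell of the array as a function of σ = pitch/distance (σ is swept by varying
the working distance at fixed pitch; sampling the central cell isolates the
inter-LED ripple from the finite array's edge falloff).  Uniformity is ~1
for σ ≪ 1, degrades monotonically (to numerical tolerance) as σ grows, and
σ = 1 is far more uniform than σ = 10.  The stated numeric threshold for
"80% uniformity" is validated only by these orderings, not as a target,
because the pitch-to-distance accounting in its source is internally
inconsistent.

## Desk-scale problem sizes

Simulations: 64^2 grid (240 µm spacing), dt 0.1 ms for corpus and loop work;
128^2 at dt 0.005 ms for the recording-arithmetic check; 256^2 at dt
0.01–0.02 ms for CV calibration.  Corpus: 56 accepted samples, 448 windows.
Training: 20 epochs, batch 8.  Closed loop: 20 paired fixtures, 5 s and 12 s
horizons, at most 3 attempts.  These sizes are the package's defaults for a
single-CPU workstation; every one of them scales up by config.
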