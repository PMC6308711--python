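# Methods

## Problem and model

A low-cost insole instrumented with six force-sensing resistors (FSRs)
cannot measure the vertical ground reaction force (GRF) or the centre of
pressure (CoP) directly: the sensors cover only small patches of the sole,
respond nonlinearly, and drift with load history.  The classical baseline,
the weighted-mean approach (WMA), estimates the CoP as the channel-weighted
mean of the *fixed* sensor coordinates

    x_wma = Σᵢ vᵢ xᵢ / Σᵢ vᵢ ,

a convex combination that provably cannot leave the convex hull of the six
sensor positions, while the true CoP routinely does (toe-off, heel rock,
extreme weight shifts).

The virtual-force estimator removes both limitations.  The insole is
divided into six anatomical areas A–F, each assigned a *virtual force*
F_E (the total vertical force over the whole area) and a *moving
coordinate* (x_E, y_E) (the pressure centroid within the area).  Eighteen
independent single-hidden-layer tanh regressors map an 18-element input
vector — the six conditioned channel magnitudes and their first and second
backward differences — to the six forces and twelve coordinate components.
The combiners are

    GRF  = F_ET + F_ER + F_EL + F_EH + F_EC + F_ELT
    CoP  = Σᵢ Fᵢ (xᵢ, yᵢ) / Σᵢ Fᵢ      (areas with Fᵢ = 0 excluded)

with the convention that the coordinate of an unloaded area is undefined
(NaN): forces below a dead-band threshold (default 0.5 N, configurable)
are treated as zero and their coordinates are not estimated.  Because the
coordinates move, the CoP can leave the sensor hull.

## Signal conditioning

Each raw channel passes through a per-channel calibration

    F[i] = poly₄(v[i]) + g · ∫ over the trailing window of v + offset,

clipped at zero.  The 4th-order polynomial captures the FSR's static
nonlinearity; the trapezoidal moving-integral term (window default 1.0 s)
absorbs the slow loading-history component of the response (hysteresis
compensation).  The calibrated series is low-pass filtered with a causal
2nd-order Butterworth at 20 Hz (50 Hz sampling).  Causality is deliberate:
the pipeline must run frame-by-frame in a 20 ms loop, which rules out
zero-phase filtering; the filter state is initialized to the steady state
of the first sample so a series that begins loaded produces no start-up
transient.  The analogue front-end of the physical sensor (RC filtering,
ADC behaviour) is not modelled; its noise-shaping role is subsumed by the
simulator's noise model.

Derivatives are backward differences (d1[i] = (m[i]−m[i−1])/dt,
d2[i] = (m[i]−2m[i−1]+m[i−2])/dt²) computed on the *filtered* magnitudes —
second differences amplify noise by 1/dt², so differentiating raw channels
would be useless.  Warm-up frames carry zero derivative slots rather than
being dropped, keeping feature and reference streams aligned 1:1.

## Regressors and training

Each regressor is a single hidden layer of hyperbolic-tangent units with a
tangent-sigmoid *output* unit as well; hidden widths default to 10 for
force nets and 200 for coordinate nets.  Since the output is bounded,
inputs are affinely scaled per feature to [−1, 1] and targets to
[−0.9, 0.9], both fitted on the training split only; predictions are
inverse-mapped.  Data are split 70/15/15 (train/validation/test) by
seeded frame-level random permutation.

Training is batch nonlinear least squares with early stopping (patience 6
validation checks):

* **Levenberg–Marquardt** (damped Gauss–Newton with the analytic residual
  Jacobian, Marquardt diagonal scaling, adaptive damping) for nets whose
  parameter count permits dense normal equations — the 201-parameter force
  nets.  Validation is checked every accepted step.
* **Chunked L-BFGS** for the 4001-parameter coordinate nets, where forming
  J'J would dominate runtime; validation is checked every 25 iterations.
  Coordinate nets default to a 300-iteration budget: at width 200 the
  validation error plateaus well before that, and the remaining budget is
  runtime without accuracy benefit.  Force nets keep a 1000-iteration cap.

Both optimizers are deterministic given the seed (initialization and split
are drawn from `numpy.random.default_rng(seed)`), so retraining with the
same seed reproduces held-out errors to floating-point accuracy.
Coordinate nets are trained only on frames where the reference area force
is nonzero, mirroring the undefined-coordinate convention.  Constant
targets short-circuit to a constant predictor with a warning.

## Synthetic study conditions

The simulator stands in for a high-resolution in-shoe pressure reference
system.  Plantar pressure is an isotropic 2-D Gaussian kernel (σ = 2.5 cm)
whose centre and total load follow task profiles emulating the five-task
acquisition protocol at 50 Hz:

| task  | load on instrumented foot | kernel-centre path |
|-------|---------------------------|--------------------|
| scan  | 0.5 × body weight, constant | counter-clockwise ellipse over the full insole (10 s period) plus anterior–posterior back-and-forth (3.7 s) |
| gait1 / gait2 | two-peak stance profile, peaks ≈ 1.1 × BW, valley ≈ 0.75 × BW; zero in swing | heel (x ≈ 3 cm) to toe (x ≈ 26 cm) progression per stance; cycle 2.0 s / 1.4 s, stance fraction 0.62 |
| squat | 0.5 × BW modulated ±22 % per 6 s cycle | posterior shift of up to 4 cm at depth |
| sts   | 0.3–1.15 × half BW per 8 s cycle | posterior→anterior→rest progression |

Body weight defaults to 700 N (a ≈ 72 kg adult).  The six area rectangles
tile the 28 × 11 cm (US8) insole envelope, so integrating the kernel per
area and rescaling to the instantaneous load makes the truth streams
self-consistent by construction: the stored GRF equals the stored force
sum and the stored CoP equals the force-weighted mean of the stored area
centroids (truncated-Gaussian centroids, always inside their rectangles).
Forces below 0.05 N are floored to zero and their coordinates marked
undefined.

The sensed stream degrades the truth three ways, in order:

1. **Sensing-area truncation** — each channel integrates the kernel over a
   square patch centred on its sensor (half-side 2.25 cm, matching the
   ≈ 20 cm² sensing area of the thin-film sensor it emulates, clipped to
   stay inside the area rectangle), times a fixed per-channel calibration
   gain.  The gain is the largest factor that keeps the calibrated patch
   reading at or below the area force for every kernel position (minimum
   area-to-patch mass ratio over a 0.25 cm grid, with a 2 % margin) —
   i.e. the channel is calibrated against an on-sensor load and
   underestimates everything else, which is exactly the "limited sensing
   area" defect the virtual forces are meant to overcome.
2. **Hysteresis** — a first-order lag with an 80 ms loading time constant
   and a 1.1× slower unloading branch.
3. **Noise** — additive Gaussian, σ = 1 % of body weight per channel,
   clipped at zero.

The underestimation property is exact at stage 1 (patch ⊂ area and
positive kernel); the lag can transiently exceed the instantaneous truth
during fast unloading, so the property is asserted on the stored
truncation-stage stream.

What the simulator does *not* reproduce: real plantar-pressure
distributions are multi-modal (heel + metatarsal heads simultaneously),
foot-shape specific, and shear-loaded; FSR noise is neither Gaussian nor
load-independent; and a real reference system has finite spatial
resolution.  Passing the synthetic recovery tests therefore demonstrates
that the estimation machinery recovers a known smooth channel-to-state
mapping under realistic degradations — not that the trained networks
transfer to any particular human subject.

## Evaluation

GRF error is the per-frame RMSE in newtons (swing frames included as
zeros); CoP error is the planar Euclidean-distance RMSE reported in
millimetres, with per-axis RMSEs and Pearson correlations alongside.
Frames where either stream's CoP is undefined (unloaded foot) are excluded
from CoP metrics and the exclusion count is reported — the weighted mean
is undefined at zero load.  Task averages are unweighted means.

The capacity scan trains one six-net force set per hidden width with a
shared seed; the data-amount scan draws balanced training sets of
increasing size and scores all of them against one fixed evaluation set,
which makes errors comparable across sizes.

## Problem sizes and defaults

The study-scale configuration trains on 15,000 frames balanced across the
five tasks (3,000 each), drawn from 70 s trials, and evaluates on held-out
25 s trials with unseen noise seeds.  Training all 18 regressors takes a
few minutes on one CPU core.  Unit and property tests use deliberately
smaller nets and shorter trials; the reduced sizes are stated in the test
fixtures.

## Known limitations

* The virtual-force inversion amplifies channel noise wherever the
  pressure kernel sits far from every sensing patch (mid-forefoot
  positions): area D's force error dominates the GRF error budget there.
* Correlation coefficients on near-constant references (scan-task GRF,
  which the simulator holds at half body weight) are close to zero by
  construction and are reported but not meaningful.
* The y-axis CoP correlation is systematically lower than x — the lateral
  span of the insole (11 cm) is small relative to the kernel width, the
  same span effect reported for medial–lateral CoP estimates generally.
* Shoe-size normalization is out of scope; the geometry is a US8 insole.
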