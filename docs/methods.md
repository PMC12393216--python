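# Methods

This note documents the models implemented in `rheo`, the parameters that
matter, what the synthetic-data generators emulate, and the numerical
choices made where the design was genuinely open.

## Flow-chamber physics (`rheo.chamber`)

The flow cell is a shallow rectangular channel (width w = 1.5 mm, height
h = 0.1 mm, length 25 mm) driven by a syringe pump at volumetric rate Q,
filled with buffer of dynamic viscosity μ = 0.40 × 10⁻³ Pa·s (water at
70 °C) and held at T = 343.15 K.  Two closed forms are exposed:

* wall shear stress  σ_S ≈ 6Qμ / (w h²),  valid for h ≪ w;
* cross-section mean flow speed  v̄ = Q / (w h).

At Q = 1.0 μl/s these give 0.16 Pa and 6.7 mm/s.  Because surface-attached
cells sit deep inside the boundary layer, the speed they actually
experience is calibrated empirically: the initial speed of cells that
spontaneously detach is regressed on pump rate through the origin (zero
flow ⇒ zero speed; slope = Σqv/Σq² in closed form), and the fitted line
converts any pump rate to a near-surface speed.

**Apparent spring constant.**  A vertically attached cell wobbles about
its pole tether ("flapping").  Treating each horizontal axis as an
independent harmonic degree of freedom in thermal equilibrium,
equipartition gives k = k_B·T / var(x) per axis; the estimator reports
per-axis values and their arithmetic mean, in pN/nm.  The choice of 1-D
per-axis equipartition (rather than radial 2-D) is a documented
convention; it reproduces the measured magnitudes at 343 K, and the
two conventions differ only by the axis-averaging rule for isotropic
tethers.  At least 100 samples are required; zero variance raises rather
than returning infinity.

**Attachment force.**  F = γ·v with a caller-supplied translational drag
γ (pN·s/μm) and the detachment flow speed v.  A Stokes-sphere helper
(γ = 6πμr) provides an order-of-magnitude default; the published
estimates used a body-shape-specific drag not reproduced here, so γ is
deliberately an input, not a constant.

## Trajectory analytics (`rheo.tracks`)

Tracks are uniformly sampled planar positions (μm, 1-s frames by
default).  All quantities are endpoint-based ("net displacement", not
path length) and measured against the upstream unit vector.

* **Three-class rule** (1-min window): positive rheotaxis = net rate
  ≥ 1 μm/min with trajectory angle ≤ 60° from upstream; negative = ≥ 1
  μm/min at ≥ 120°; random otherwise.  Thresholds are inclusive.
* **Five-class flow-response rule** (3-min window), fixed precedence
  detached > dragged > rheotaxis > stationary > free:
  detached = downstream ≥ 13 μm/min at angle ≥ 120°; dragged =
  downstream ≥ 1 μm/min at ≥ 120° **and** an attachment-persistence
  qualifier (≥ 3 μm downstream and ≤ 10 μm perpendicular per 3 min) —
  tracks failing the qualifier are not surface-associated and fall to
  *free*; stationary = |along| ≤ 1 and |perpendicular| ≤ 5 μm/min.
  The source legend for this scheme is ambiguous (it lists two
  "detached" clauses); the precedence above is this package's documented
  resolution and is stable under test.
* **Diffusion.**  The pooled time-averaged MSD over all tracks is fitted
  through the origin, MSD(τ) = 4Dτ, by weighted least squares (weights =
  pair counts) over lags up to ¼ of the shortest track.  A quadratic term
  is co-fitted as a diagnostic: when b·τ_max² exceeds the linear
  contribution the fit is flagged `drift_dominated` (ballistic motion adds
  (vτ)² to the MSD and the Brownian estimate is then unreliable).  An
  optional per-track constant-velocity subtraction (`remove_drift`) sends
  pure-drift tracks to D ≈ 0.  Pooling (not per-cell averaging) is the
  default; per-cell estimates can be obtained by calling the fitter per
  track.
* **Reversals.**  The along-upstream frame velocity is smoothed with a
  30-s moving average; a reversal is a sign change whose new direction
  persists ≥ 30 s (shorter excursions are ignored).  Both windows are
  package defaults, exposed as arguments; only the headline pooled rate
  (one per 100 min) is constrained by the study.  Pooled rate = total
  reversals / total track minutes.

## Pilus filament statistics (`rheo.pili`)

Filament angles θ are measured from the flow direction and wrapped to
[0, 360).  The orientation ratio is count(θ ∈ [0,90] ∪ [270,360)) /
count(θ ∈ (90,270)); the boundary angles 90° and 270° belong to the
against-flow numerator (closed intervals — a convention the source does
not state; it is configurable via `closed_boundaries`).  Rose histograms
require the bin width to divide 360° and conserve total counts.  Length
and per-cell-count moments are plain population statistics (SD with
ddof = 1).

## Bead-assay segmentation (`rheo.beads`)

Traces are bead-to-pole distances r(t) at 0.1-s sampling.  The published
analysis keeps "directional movements of more than 0.5 s"; the
segmentation algorithm behind that criterion is this package's own:

1. fit a line in every sliding 0.5-s window (6 samples);
2. judge each sample by the **lowest-residual window covering it** —
   near a pause/run kink the flat-side window wins for pause samples and
   the in-run window for run samples, which keeps boundaries sharp to
   about one frame (marking every sample of every accepted window
   instead lets kink-straddling windows of slow runs pass the residual
   cap and biases slow velocities low by ~10%);
3. a sample is directional when its best window has |slope| ≥ 0.2 μm/s
   and residual RMS ≤ 50 nm;
4. maximal same-sign runs of directional samples ≥ 0.5 s become
   segments, re-fit over their full extent.

Sign convention: negative = toward the pole (retraction proxy).  Event
frequency counts segments starting within 10 s of the first segment's
start; a trace with no segments raises (undefined is not zero).  The
thresholds live in `SegmentationConfig`; segmentation is deterministic
and idempotent.

## Tug-of-war simulator (`rheo.tugofwar`)

A vertically attached cell is a rigid prolate spheroid (semi-axes
a = 1.25, b = 0.5 μm) pivoting about its attached pole, which is fixed on
the plane.  The tilt is confined to a vertical plane: the internal
coordinate is the axis angle α from the surface (α = 90° vertical), and
the reported θ_c = min(α, 180° − α) ∈ [0°, 90°].

Each pilus is a linear spring (stiffness κ_p) from an emanation point at
offset b along the axis to an anchor on the plane; the motor moves its
equilibrium length ℓ (extension +v_ext, retraction −v_ret), and tension
is κ_p·max(0, L_geometric − ℓ).  Per time step: motor update → tension →
detachment of any pilus above the force limit F_rmax → overdamped tilt
dα = m_rot·τ·dt (re-checking the force limit at the new angle, so no
output state carries tension above F_rmax) → nucleation → scheduled mode
switches.  Filaments switch between extension and retraction after
exponential dwells (mean τ = 1 s each way); fully retracted filaments
disappear; nucleation is a feedback process (rate ∝ deficit from the
target count n_pili, divided by the attachment probability) so the mean
attached complement stays at the measured per-strain value.  New
filaments attach taut (zero tension) at a random azimuth, at a planar
distance drawn exponentially with the strain's mean filament length.

Two torque sources act about the pivot: the pilus springs, and a
righting torque κ_tilt·n_attached·(π/2 − α) from the polar adhesion web —
each attached filament contributes a fixed share of rotational anchoring
of the pole contact.  Without this term the flat state θ_c = 0 is
absorbing (every lever arm vanishes when both the emanation point and all
anchors lie in the plane), which contradicts the observed recovery of
tilted cells; with zero attached filaments the term vanishes and the
angle is frozen, as required for an unanchored pole.

**Why the strains differ.**  Over one retraction dwell a filament builds
tension ≈ κ_p·v_ret·τ.  With κ_p = 50 pN/μm and F_rmax = 100 pN this is
~152 pN for the wild-type motor (v_ret = 3.04 μm/s) — filaments routinely
hit the force limit, detach, and release stored web deflection, producing
occasional large tilts — but only ~64 pN for the ΔpilT2 motor
(1.27 μm/s), whose filaments stay attached and keep the web balanced.
Together with ΔpilT2's larger filament complement (13.4 vs 7.6) this
yields a strictly smaller angle SD for ΔpilT2 at matched seeds (ratio
≈ 1.35 at the defaults), and the two monotonicity trends: variability
non-increasing in filament number, non-decreasing in v_ret/v_ext.  A
pilus stiffness of order 1 pN/μm would cap tension at κ_p × filament
length ≈ 10 pN, far below any plausible F_rmax, rendering force-limited
detachment inert; κ_p = 50 pN/μm is the smallest round value for which a
blocked retraction crosses F_rmax within a dwell.

**Calibration.**  m_rot = 0.3 rad/(pN·μm·s) and κ_tilt = 20 pN·μm/rad
per filament were calibrated once so that the wild-type preset's free-pole
displacement SD (2a·sd(α)) matches the ~0.3 μm flapping amplitude implied
by the measured wild-type spring constant at 343 K.  Integration is
explicit Euler at dt = 10 ms with output every 100 ms and a per-step
|dα| ≤ 0.1 rad guard; per-cell seeds are spawned deterministically from
the ensemble root seed, and runs are bit-reproducible for fixed
(params, seed).  Angle variability is summarized as the circular SD of
θ_c (degrees); for the concentrated distributions involved it is
numerically close to the ordinary SD.

The supplementary equations and parameter tables of the published model
were not available to this implementation; the simulator reproduces the
main-text description and its qualitative claims (strain contrast and
monotonicities), not the published histograms numerically.  Flow-induced
torque is deliberately absent: the simulated scenario is flapping without
flow.

## Synthetic data (`rheo.synth`)

Generators are pure functions of (spec, seed) and emulate the statistical
structure of the study's inputs; they do not emulate microscopy artefacts
(detection noise in tracking, drift, blinking), so passing tests
demonstrate correct analytics on clean moment-matched data, not robustness
to image-processing errors.

Distribution families (only means ± SDs are published, so families are
this package's choice):

* **Bounded positive quantities** (drift rates above the class floor,
  bead-run speeds above the detection floor, per-cell filament counts
  ≥ 1): shifted gamma, lower + Gamma(shape, scale), with shape and scale
  solved in closed form so the realized mean/SD equal the printed values
  exactly.  A truncated normal cannot represent several of these targets
  at all — for the downstream drift (9.3 ± 18.0 μm/min above a floor)
  the required (mean − lower)/SD < 1 is below the family's attainable
  minimum (the exponential-tail limit).
* **Filament lengths**: gamma matched to 2.8 ± 3.0 μm (WT) and
  4.5 ± 4.4 μm (ΔpilT2) — the printed SD exceeds the mean, ruling out a
  normal.  **WT filament angles**: wrapped normal about upstream with
  σ = 90°/Φ⁻¹(0.875) ≈ 78.2°, chosen so the expected against/toward
  orientation ratio is 3; ΔpilT2 angles are uniform.
* **Flapping**: i.i.d. Gaussian per axis with variance k_B·T/k.
* **Reversals and bead events**: Poisson.

**Track cohort archetypes.**  Three study conditions are presets:

* `no_flow` — every cell freely Brownian at D = 1.7 μm²/s (the no-flow
  motility measurement).
* `flow_mixture` — 50/40/10 positive/negative/random.  Drifting cells
  move at a per-cell rate from the class's moment-matched family
  (17.1 ± 11.0 upstream; 9.3 ± 18.0 downstream) with a small residual
  wander D_res = 0.02 μm²/s: in-flow rheotactic tracks are nearly
  rectilinear (millimetre-scale upstream runs over an hour), which free
  diffusion at 1.7 μm²/s would destroy.  The class floor is 3 μm/min —
  about twice the endpoint-noise rms of a 1-min window at D_res — so that
  class identity is well defined under measurement noise; moment matching
  keeps the realized class means at the printed values.  The "random"
  class is a confined wiggler (jitter SD 0.3 μm, the flapping amplitude
  scale): a free Brownian walker at 1.7 μm²/s covers ~18 μm/min and would
  be classified positive/negative/random at 1/3 each by chance, which no
  mixture could survive.
* `reversal_cohort` — 100 cells × 100 min of constant 17.1 μm/min
  upstream drift with Poisson reversals at 0.01/min (10⁴ track-minutes),
  the condition under which the pooled reversal interval of ~100 min is
  recovered.

**Bead traces** alternate pauses and constant-velocity runs (one
away/toward pair per trace by default), with 20 nm Gaussian localization
noise; run speeds are drawn ≥ 0.35 μm/s (the segmentation threshold plus
~1.5 σ of window-slope noise) and run durations 0.8–1.6 s, because the
printed statistics describe *detected* directional movements, which are
bounded away from the detection limits by construction.

CSV is the single interchange format; floats are written at 17
significant digits and parsed with round-trip precision, so write → read
restores bit-identical values and regeneration at a fixed seed yields
byte-identical files.

## Problem sizes in the test suite

The bundled tests run the recovery checks at reduced but statistically
adequate sizes: 50 tracks × 60 s for diffusion, 200 tracks for drift and
mixture proportions, 5000 flapping samples, ~240 bead runs per direction,
10⁴ track-minutes for reversals, 100 cells × 100 s per strain for the
simulator contrast (20 cells per grid point for the monotonicity sweeps),
and one full-scale 500 cells × 1000 s ensemble at coarse integration
(dt = out_dt = 0.1 s) for the sample-count check.

## Known limitations

* The simulator's mechanical defaults (κ_p, F_rmax, κ_tilt, m_rot) are
  package choices calibrated to one observable (flapping amplitude); only
  the qualitative contrasts should be read from it.
* The equipartition estimator assumes a harmonic, equilibrated tether and
  uncorrelated samples; slow drift in a real trace inflates the variance
  and underestimates k.
* The reversal detector needs drift above the smoothed noise floor
  (roughly 2·√(2·D_res/window)); near-threshold movers are not reliably
  scored, which is why the reversal cohort uses the class-mean drift.
* The five-class flow-response precedence is an interpretation of an
  ambiguous legend (see above) and is therefore configurable code, not
  ground truth.
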