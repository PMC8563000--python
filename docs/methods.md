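# Methods

`bandwave` models and measures the single-cell behavior that holds a
chemotactic *E. coli* band together while it migrates.  This note records
the models, the parameter choices, and the numerical decisions, in the
order the analysis uses them.

## The physical picture

A dense band of cells consumes aspartate and chases the gradient it
creates, translating at a constant group speed `V_G` (~0.15–0.18 mm/min).
In the co-moving band coordinate `z = x − V_G t − x_peak(0)` every cell is
a run-and-tumble random walker whose *expected drift velocity*

    V_D(z) = ⟨l_R cos θ_R⟩ / ⟨τ_R + τ_T⟩

(the mean axial displacement rate of tumble-then-run events starting at
`z`) decreases from the back of the band to the front and crosses `V_G`
inside it.  Writing the motion as a Langevin equation
`dz = [V_D(z) − V_G] dt + ε dW` and linearizing the perceived gradient,
`g(z) ≈ g0 + g1 z` with `V_D = χ g`, gives an Ornstein–Uhlenbeck process

    dz = [χ(g0 + g1 z) − V_G] dt + ε dW

with reversion rate `r = χ|g1|`, balanced position
`z* = (V_G − χ g0)/(χ g1)`, and stationary SD `σ = ε/√(2r)`.  A decreasing
gradient (`g1 < 0`) makes the front a *pushed* wave: each phenotype is
mean-reverting about its own `z*`, which orders a diverse population by
chemotactic ability χ and keeps the group compact.  `g1 = 0` gives plain
diffusion (σ² growing like `2Dt = ε²t`) and phenotype separation;
`g1 > 0` (pulled) diverges.

Sign conventions in the closed forms are fixed by their defining
conditions rather than any typeset formula: `F(z*) = 0`, `−U′(z) = F(z)`,
stationary variance `ε²/(2r)`, diffusive law `σ = √(2Dt)`.  The potential
`U` is an upward parabola for a pushed front, so its additive constant is
fixed by `U(z*) = 0` (a value at infinity does not exist); the
velocity-integral variant `U(z) = ∫_z^∞ V_D dz′` is provided separately as
`drift_potential` and is labeled by its different units (mm²/min).

## Canonical units and formats

Millimetres and minutes everywhere in memory; conversion only at I/O.
Tables are CSV with unit-suffixed column names and a `#` comment header
carrying the seed and config hash.  Analysis bins are 240 µm (60 µm for
peak finding), the channel cross-section is 12,000 µm², and the camera
frame interval is 1/(9 fps) ≈ 0.11 s — the tracking geometry the
synthetic data emulate.

## Synthetic run-and-tumble bands

The generator produces 2D lab-frame tracks from alternating tumbles
(zero displacement, exponential duration, mean 0.2 s) and straight runs
at 20 µm/s (exponential duration, base mean 0.8 s), sampled on the camera
grid.  Drift is imposed by direction-dependent run durations: a run at
angle θ starting from a tumble at `z` has mean duration
`τ_R0 (1 + b(z) cos θ)` with

    b(z) = 2 V_D(z) (τ_R0 + τ_T0) / (v τ_R0),

which makes the event-level statistic equal `V_D(z)` *exactly* in
expectation (⟨cos²θ⟩ = ½ for uniform reorientation).  |b| ≥ 1 would
require negative durations, bounding the attainable drift; the generator
raises an error rather than saturating.  With heading persistence enabled
(off by default) the calibration identity no longer holds exactly.

The reference study condition is 500 cells tracked 10 min with
`V_D(z) = −0.05 z + 0.17` mm/min and `V_G = 0.18` mm/min, the initial
band (SD 0.39 mm, the quasi-stationary spread of this process) centered
at the frame origin.  Centering at the origin rather than at the drift
crossing mirrors the experimental geometry, where the crossing sits
~0.2 mm *behind* the density peak because cells leak out the back; a
symmetric stationary band would instead center on its crossing and the
intercept of the drift fit would coincide with `V_G`.  The small residual
relaxation of the band mean (≈0.08 mm over 10 min) biases the plain
⟨Δx/Δt⟩ group-velocity estimate downward by ~4%, which is why stationary
configurations (`V_D0 = V_G`) are used when the group velocity or the
flatness of the instantaneous velocity is itself the quantity under test.

What the generator does **not** emulate: detection noise, track
splitting/merging, cell-cell collisions, run-speed variability, and the
density skew of a real Keller–Segel band.  Passing recovery tests
therefore certify the *estimators* under ideal tracking, not robustness
to imaging artifacts.

## Segmentation

Tumbles are detected on lab-frame step speed and turn angle: a step is a
tumble candidate if its speed falls below 0.5× the reference run speed
(75th percentile of all step speeds), or turns by more than 90° at below
0.8× the reference; hysteresis then erases tumble segments shorter than
2 frames and run segments shorter than 2 frames.  All thresholds are
parameters.  Tumbles near one frame in duration are irrecoverable at
9 fps; the drift statistic is insensitive to these misses because merging
tumble-run elements preserves both the summed axial displacement and the
summed duration, which is all `V_D` uses.  Frame-level agreement with
generator ground truth is ≥ 90% at defaults (measured ~96%).

## Profiles and fits

`V_D(z)` bins events by tumble position; its SEM is a seeded
nonparametric bootstrap over events (200 resamples).  The linear fit is
weighted least squares against the *occupancy-weighted mean* tumble
position per bin (using bin centers under uneven occupancy attenuates the
slope by ~Δz²/12σ²); parameter SEs are scaled by √(χ²/dof) when the
residuals overdisperse.  The fit window is the central ±1.65σ of the
density profile (~90% of cells).  The frame origin is the t=0 density
peak (60 µm bins, boxcar-smoothed over 5 bins, parabolic refinement);
its bootstrap uncertainty is propagated into the intercept SE as `r·δ`.

## Gradient inference

The travelling-wave attractant balance `D_s S″ + V_G S′ = k ρ` with
`S′ → 0` behind and `S → S_far` ahead is discretised by second-order
central differences and solved as a sparse linear system; a cell Péclet
number ≥ 2 raises a refinement error.  Defaults: `D_s = 0.048` mm²/min
(aspartate), `S_far = 200` µM (the medium), MWC constants
`K_off = 3.5` µM, `K_on = 1000` µM (Tar–aspartate; only the *shape* of
`g = d/dz ln[(1+S/K_off)/(1+S/K_on)]` matters downstream, and `g` is
exactly invariant under a common rescaling of S, K_off, K_on).  The
consumption constant is normalized per cell of *instantaneous* number
density; the pooled multi-frame density is divided by the frames-per-cell
before inference.  The default `k = 8.5e-4` µM·mm³/min per cell is sized
so the 500-cell demo band depletes the 200 µM field to ~K_off behind
itself — the regime in which the perceived gradient actually decreases
across the band.  (Per cell it is larger than a physiological uptake rate
because the synthetic band carries ~500 cells where a real band carries
~10⁵.)

## Langevin ensembles

Euler–Maruyama at fixed dt (default 0.005 min; an error is raised when
`dt·max(χ|g1|) > 0.1`).  Chemotactic drift is capped at the swimming
speed (1.2 mm/min), which matters only where a depleted field would
otherwise produce unphysically steep log-gradients.  Field-coupled runs
advance the attractant by operator splitting: zeroth-order consumption
(clipped at S = 0, counted) then Crank–Nicolson diffusion with no-flux
ends, on a 20 µm grid.  Particle ends are absorbing with leak accounting
in consumption mode — cells shed behind the band are a real feature — and
reflecting in trail mode.  Band speed is measured by tracking the
smoothed density peak with a continuity window (±1.5 mm per snapshot) so
the tracker is not captured by the shed-cell pile, then fitting peak
position on time.

The trail-following variant replaces consumption by secretion
(`+β ρ`, optional first-order decay).  Without decay the trail saturates
the receptors (S ≫ K_on) where the group has been, so the only
perceptible gradient is at the trail's leading edge; the group creeps
outward riding that saturation front, and phenotype means order with the
*opposite* sign to the consumption case — higher-χ cells are held closest
to the accumulated signal.  This is a minimal, documented stand-in for a
secretion-coupled model whose exact form is open; its tests assert the
behaviors this stand-in robustly produces (advance of the group, strict
ordering, linear response of S to β under decay).

## Agent-based pathway model

Standard MWC receptor cluster + linear adaptation + Hill motors, 3D, in
the 20 × 0.6 × 0.02 mm channel with reflective walls:

* free energy `f = N[α(m0 − m) + ln(1+S/K_off) − ln(1+S/K_on)]`,
  activity `a = 1/(1+e^f)`, adapted activity `a0 = 1/3`;
* adaptation `dm/dt = (a0 − a)/(τ N α a0(1−a0))`; the slope normalization
  makes τ (default 10 s) the relaxation time of the *activity* for every
  gain, so N changes only the amplification of the gradient signal —
  measured χ is linear in N (χ ≈ 0.054·N mm²/min at defaults) while the
  zero-gradient motility D is N-independent;
* `Yp = Yp0·a/a0`; each of 5 flagella is a two-state CW/CCW Markov
  process (switching scale 180/min, giving ~0.8 s runs) whose CW bias is
  a Hill function of Yp (H = 10) with the half-point calibrated so that
  basal Yp reproduces the basal tumble bias TB0 = 0.2 through the voting
  rule (tumble iff ≥ 2 flagella CW);
* runs at 20 µm/s with optional rotational diffusion; uniform
  re-orientation when a tumble ends.

Pathway constants other than the manipulated knobs (N, τ, Yp0/TB0) are
conventional choices exposed in `PathwayParams`; the claims tested are
emergent statistics that are robust to them.  The χ ladder for
figure-level experiments is N = 3.7, 4.6, 5.5, 6.4 (χ ≈ 0.2–0.35
mm²/min), simulated against a rigid moving profile
`S = √(K_off K_on)·exp(g0 z + g1 z²/2)` (perceived gradient ≈ `g0 + g1 z`
in the sensitive range; defaults g0 = 0.9/mm, g1 = −0.45/mm²,
V_G = 0.15 mm/min), or against a consumption-coupled 1D field.
`effective_chi` measures χ as drift/gradient in a shallow static
exponential profile and D from the zero-gradient MSD slope.

## Problem sizes

Simulation sizes in tests and the acceptance script are chosen to give
3–5σ margins on every monotonicity or recovery assertion at a few minutes
of single-core compute: the recovery ensemble is 500 cells × 10 min
(~2.7 M samples, ~190 k events), ensemble property checks use 4–10 k
particles (10⁵ for the distribution-equivalence check), and the agent
ladder is 4 × 200 agents × 45 min.  Statistical tolerances are stated in
the tests as multiples of the relevant standard error; fixed seeds make
the suite deterministic.

## Known limitations

* The segmentation stand-in is validated on synthetic ground truth, not
  against the cluster-based classifier used on real movies.
* The OU picture is exact only for a linear gradient; the agent ladder's
  effective χ in a moving profile runs ~20% above the static-probe χ
  (adaptation lag), so closed-form positions are compared at the level of
  ordering and monotonicity, not absolute placement.
* The consumption PDE uses zeroth-order kinetics clipped at S = 0;
  saturating kinetics would smooth the depleted tail.
* No cell growth, cell–cell interaction, or oxygen/secondary fields.
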