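# Methods

## Scope and model structure

`cocorod` models the trunk of a coconut palm as a growing Cosserat rod in
three configurations: *reference* (material as deposited), *relaxed*
(external forces removed) and *current* (loaded). Primary growth is
apical elongation with tropism-steered curvature; secondary growth is a
static exponential taper of the radius with height, anchored at the
diameter at breast height (DBH, 1.4 m). The two are coupled through the
trunk geometry: the taper supplies cross-section area, line density and
flexural rigidity to the apical force balance.

## Rod kinematics

Directors evolve by `∂ᵣfᵢ = y × fᵢ` with body-frame strains, and the base
curve by `∂ᵣs = Σ wᵢ fᵢ` (unsheared reference `w = (0,0,1)`). The frame
ODE is integrated by fixed-step classical RK4 on the user grid (default
spacing 0.01 m) with Gram–Schmidt renormalization after every step;
constant-curvature inputs match the closed-form rotation to better than
1e−6 relative at 1e−3 m steps, and orthonormality is preserved to 1e−9.
The trunk-length schedule `k(t)` is available both as the analytic
constant-velocity form `a_v t` and as a validated monotone table.

## Tropism strain seeding

New apical material receives curvature `β⁰`, curvature gradient `dβ⁰/dr`
and twist `γ⁰` from projecting a second-order Taylor expansion of the
growth director onto the current triad, with target direction `f_p^F`.
Conventions:

* `f_p^F = normalize(f_p cos θ + f_p^β sin θ)` — the rotation of the
  gravitropic preferred direction toward the in-plane normal `f_p^β`.
  A strict-literal mode exposing the raw cross product
  `(f_p cos θ) × (f_p^β sin θ)` exists for inspection; it is degenerate at
  θ ∈ {0, π/2} and is not used by the simulator.
* `sgn(0) = +1`; the square-root argument `2(1 − c₃)` is clamped at 0
  against rounding; `β_max = 0` yields identically zero strains (straight
  growth), which is the shipped default.
* The projected quadratic system is solved *exactly* when
  `β_max = 2/Δ` (the curvature bound saturates the look-ahead `Δ`); unit
  tests assert machine-zero residuals there. For a Δ-independent
  `β_max`, the meaningful consistency statement is that the projection
  relations are the degree-2 Taylor polynomial of the propagated director
  under the seeded strain field: the residual against exact (batched RK4)
  propagation decays at third order in Δ, verified empirically over
  random targets and frames (order ≈ 3 across Δ ∈ {0.1, 0.05, 0.025} m).

## Apical system

Per explicit-Euler time step (default dt = 0.05 y): the contact couple is
integrated inward from the free tip (`∂ᵣq = −p_y cos θ`, `q(k) = 0`), the
relaxed curvature updated by `∂ₜβ* = (∂ₜYI) q/(YI)²` (new wood freezes in
the loaded shape), then the angle outward from the clamped base
(`∂ᵣθ = β* + q/YI`, `θ(0) = θ₀`) and the planar base curve by the
linearized direction rule. Newly appeared material receives
`β* = β_max sin((θ_p^f − θ₀)/2)`.

The transverse load defaults to the *projected* self-weight
`p_y = ρ‴ g sin θ` plus an optional wind line load. The projection
matters: a perfectly vertical trunk carries its weight axially and must
not bend under it — with the unprojected line density a vertical rod
would curve spontaneously, contradicting the degenerate vertical-growth
case the model is anchored on.

The flexural rigidity uses the mass-weighted frustum second moment
evaluated per material point; that expression is singular where the local
radius equals the base radius, so the simulator floors the radius gap at
1e−6 m, making the rigidity finite and very large at the clamped base
(which damps nothing physical). `∂ₜYI` follows from the moment's linear
dependence on trunk length: `∂ₜ(YI) = YI · a_v / k`.

Time units are years in all growth modules and seconds in the sensor
modules; the boundary is explicit (no hidden conversion).

## Abiotic factors

Sunlight is an additive budget `TAS = OMS + PFS + VS(H) + E` of
dimension-agnostic scalars; how a sunlight deflection angle follows from
TAS is not modelled — `θ_S` is a configuration input and TAS a
diagnostic. Wind applies a tip force to the cantilevered frustum:
`D = F k³/(3YI)`, `θ_w = arccos(clip(k/(D + x), −1, 1))` (zero when the
argument clips at 1), composing into `θ_p^f = θ + θ_S + θ_w`. The shipped
presets carry the published `θ_p^f = 0.61π` directly with `F = 0`.

Two conventions are deliberate:

* The frustum moment `I = (ρ′πk/10)·|x⁵ − x₀⁴x + x₀⁵|/|x − x₀|` keeps its
  wood-density weighting, so `YI` is a mass-weighted rigidity rather than
  the SI flexural rigidity; the package is internally consistent in that
  convention. Absolute values keep `I > 0` for tapered trunks. The
  quintic is *not* symmetric under swapping the radii; only positivity is
  guaranteed for either ordering.
* The expanded constitutive form is implemented as the composition of
  `β = β* + q/YI` with the frustum moment (they agree to 1e−12 by
  construction), not as an independent formula.

## Secondary growth

`x(k) = √(λ e^{−ak})` with `a = ρ′g/B`, `λ = (−ρ′g/(Bπ))c′`. Only the
composites `a` and `λ` are identifiable, so admissibility is `λ > 0`
rather than sign constraints on `B` and `c′` individually (the bulk
modulus carries a built-in sign convention). `calibrate_taper` inverts
two anchor radii exactly: `a = (2/h)ln(x_base/x_h)`, `B = ρ′g/a`,
`c′ = −(Bπ/ρ′g)x_base²`. The radial velocity is the chain-rule derivative
`V^r = −(a/2) x a_v`, negative for a tapered trunk (a material point sits
on an ever-longer trunk); the direct closed form and its Γ/ζ-substituted
variant agree to 1e−12, and both match a central time difference of the
radius to 1e−6. Breast height defaults to 1.4 m and is configurable.

The WCT and CGD cultivars are pure parameter presets. Their physical
constants are the published experimental set; the taper anchor radii and
the CGD apical velocity are synthetic representative values (marked as
such in the preset files) since no field anchors are published.

## Simulator and metrics

Temporal output is sampled yearly; spatial profiles every 0.1 m from
breast height to the tip at the final time. Runs are deterministic:
identical parameters give bit-identical CSVs. Comparison metrics take a
predicted and an observed series (linear resampling onto the observation
abscissa when grids differ): MAE, RMSE, `R² = 1 − SSE/SST`, and the
*variance of the error* in population form — reported in squared units,
with an optional unit scale (100 for centimetre reporting). Zero-variance
observations make R² undefined and raise.

## Sensor pipeline

* **Denoising** — Daubechies `db4`, 4 levels (capped by signal length),
  soft thresholds per detail band chosen by minimizing Stein's unbiased
  risk estimate; noise scale estimated once from the finest band as
  `MAD/0.6745`. Without thresholding the transform round-trips to 1e−10.
* **Fusion** — EKF with state
  `[h, ḣ, ḧ, h⃛, x, ẋ, ẍ, x⃛, ψ, ψ̇]`: two constant-jerk (degree-3
  polynomial) kinematic chains plus heading. Measurements per sample:
  vertical specific force minus gravity, horizontal acceleration,
  magnetometer heading `atan2(m_y, m_x)` (unwrapped), and gyro heading
  rate. Joseph-form covariance updates keep the covariance symmetric
  positive semi-definite. Diagonal initial covariances for position and
  orientation; all noise settings live in `EKFConfig`.
* **Velocity constraint** — accelerometer dead reckoning alone has an
  irreducible position random walk (≈ σ_a √dt · T^{3/2}/√3 ≈ 2 m over a
  60 s climb at σ_a = 0.05 m/s²). Since the climb is velocity-controlled,
  the commanded ascent speed may be supplied (`climb_speed`); it enters
  as a weak scalar velocity pseudo-measurement (σ = 0.05 m/s) applied
  only while the velocity estimate exceeds half the commanded speed, so
  the launch ramp and slip stalls remain governed by the accelerometer.
  This bounds the height error to ~2.5% median over seeded climbs; the
  residual bias is phantom distance accrued while a stall transits the
  half-speed gate.
* **Diameter** — `frame_span − us_left − us_right` assuming diametrically
  opposed sensors on a rigid frame of known span (a required input;
  chord-offset corrections are out of scope). Negative values are
  flagged, not fatal.
* **Rectification** — Hampel filter (window 11, 3 scaled MADs, rolling
  median replacement) on the raw diameter stream *before* wavelet
  smoothing, so isolated scar spikes are excised rather than smeared;
  isotonic regression (scikit-learn PAVA) projects the height stream onto
  monotone non-decreasing, which an ascent must satisfy. The filter
  output (not a smoother) is used throughout.
* **Extraction** — all streams are linearly resampled onto a uniform
  height grid (0.1 m, with the exact climb top appended); total height is
  the grid maximum; DBH is read at 1.4 m.

## Synthetic data

The generator emulates the study conditions: a 0.2 m/s climb sampled at
50 Hz on a calibrated frustum trunk, accelerometer noise 0.05 m/s²,
ultrasonic noise 0.005 m, two slip stalls (trapezoidal decel–hold–accel,
visible to the IMU and present in the ground truth) and three scar spikes
(isolated +0.08 m outliers on one range channel at recorded indices). One
seed fans out to six per-channel substreams, so every channel is
independently reproducible and traces are bit-identical per seed.

What it does **not** emulate — and therefore what passing recovery tests
cannot show about real climbs: IMU bias instability and temperature
drift, ultrasonic beam geometry and multipath, frame compliance and
mounting misalignment, trunk lean or non-circular cross-sections, and
magnetic disturbances. Recovery numbers here certify the pipeline's
correctness, not field accuracy.

## Problem sizes and defaults

Default simulation: 40 years at dt = 0.05 y, dr = 0.01 m (800 time steps,
~1800 grid points — sub-second runs). Sensor studies use 12 m climbs
(~3100 samples) and ten seeded trees with base radii drawn in
0.12–0.20 m and taper ratios 0.80–0.92. These sizes keep every check
deterministic and desk-scale while exercising all code paths.

## Known limitations

* The apical system is planar (small deflections); large-deflection
  statics and 3-D wind loading are out of scope.
* The taper is static in time at fixed height: DBH is constant once set
  by calibration, so temporal DBH series are flat — faithful to the
  closed-form taper this package implements.
* The sunlight submodel is a bookkeeping identity; it constrains nothing
  until a `θ_S` mapping is supplied.
* `V^r` is negative for tapered trunks under the chain-rule reading; a
  positive nominal `V^r` appears in the config only as the maturation
  velocity entering the differential-maturation curvature rate.
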