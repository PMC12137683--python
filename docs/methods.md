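# Methods

## Scope and geometry

One well of a rectangular 4-well culture plate is modelled as a flat-bottomed
channel of length L = 80 mm along the rocking direction, width W = 26 mm
(sized for a 26 × 76 mm microscope slide; the plate holds 24 mL per well at
≈ 11.5 mm depth, consistent with the 14.5 mm plate height), pivoting about the
channel mid-point ("CoC") with the tilt axis at floor level. Fill volumes
convert to depth through the floor area (5 mL → 2.40 mm, 9 mL → 4.33 mm).
Positions are measured from the CoC, positive toward the end that dips for
positive tilt. Rounded well corners and the exact pivot height are not
modelled; both are below the fidelity of the flow closure discussed next.

## Motion

The drive tilts the plate between ±α at angular speed ω (device range
±1–19°, 1–99 °/s). With unlimited stepper acceleration the tilt is an exact
triangle wave with period `T = 4α/ω`; with a finite acceleration limit `a`
the angular velocity becomes a trapezoid and `T = 4α/ω + 2ω/a` (each reversal
takes `2ω/a` but shortens the adjacent cruises by `ω/a` each); when
`a < ω²/2α` the motion degenerates to bang-bang acceleration with
`T = 4√(2α/a)`. The default is unlimited acceleration, which is also what the
speed-to-RPM factor `60/(4α)` (2.143 per °/s at α = 7°) presumes. Phase
convention: θ(0) = +α. Simulation sweeps may set speeds slightly outside the
front-panel range (e.g. 100 °/s) via `MotionSettings(..., enforce_limits=False)`.

## Flow model

Depths are 30× smaller than the channel length, so the free surface is
modelled with the 1D shallow-water equations in the co-rotating frame:

    h_t + (hu)_x = 0
    (hu)_t + (hu² + ½ g_n h²)_x = g_t h − 3 ν u / h,

g_n = g cos θ, g_t = g sin θ. The friction term and the recorded wall shear
stress τ = 3 μ u / h both come from the steady laminar parabolic velocity
profile. Rotating-frame (Euler/centrifugal) forcing is available behind
`include_euler_forcing` but off by default: at the maximum angular speed
(1.73 rad/s) those accelerations are ≲ 2 % of g.

Numerics: finite volumes with minmod-limited MUSCL reconstruction of depth,
free-surface elevation and velocity; HLL fluxes; hydrostatic reconstruction
with per-side edge beds (the uniform tangential gravity is recast as an
effective linear bed so the scheme is exactly well-balanced, shorelines
included); SSP-RK2 in time with an adaptive CFL step (default CFL 0.4);
semi-implicit friction `u ← u/(1 + 3νΔt/h²)` so thin films are
unconditionally stable; reflective walls with first-order wall cells so the
mirror-state mass flux is identically zero. Cells with `h ≤ h_min` (default
1 µm) are dry: zero velocity, zero reported shear. Volume is conserved to
round-off; a tilted lake at rest produces velocities at machine precision;
dam-break depth profiles match the closed-form rarefaction solution to
≤ 0.1 % L1 at 1000 cells and front speeds to ≈ 4 % at 3000 cells.

Default production resolution is 400 cells, 5 spin-up periods, then 1 recorded
period with shear sampled at 1 kHz (depth fields optionally at a configurable
rate). Period-averaged maps change by < 1 % between 400 and 800 cells;
instantaneous peaks by ≈ 10 %, because they live at wetting fronts and wall
run-up. The solver contains no randomness.

## What the shear magnitudes mean

The parabolic closure is exact for steady, fully developed film flow but
systematically *underestimates* wall shear during the impulsive tilt
reversals: there the true near-wall gradient forms a Stokes boundary layer of
thickness δ ≈ √(νT/π) ≈ 0.4–0.5 mm, much thinner than the 2–5 mm depth, so
the instantaneous wall stress is closer to μu/δ than to 3μu/h — a factor of
roughly h/3δ ≈ 2–3. Accordingly, the simulated 5 mL ± 7° sweep reproduces the
*structure* of resolved-CFD reference maps — period-averaged shear maximal at
mid-channel, instantaneous peaks at the channel ends, average-map resonance at
30 °/s inside the reported 25–50 °/s window — but its magnitudes sit at about
half the reference values (max period-averaged 0.24 vs 0.46 N/m²; max
instantaneous ≈ 1.0 vs 2.4 N/m²). For the same reason the model's shear
drops when depth grows (9 mL gives 0.12 N/m² averaged) whereas
boundary-layer-controlled wall stress is nearly depth-insensitive. Treat the
shear maps as structurally faithful but magnitude-calibrated only to within a
factor of ~2; the per-cell force conversion (effective area 33.3 µm², giving
15 pN at 0.46 N/m² and 80 pN at 2.4 N/m²) applies to whatever stress value is
supplied.

The instantaneous-peak map has a second caveat: at low rocking speeds the
channel drains far enough that the advancing front runs over nearly dry bed,
and τ = 3μu/h spikes in the thin cells at the contact line. These spikes are
resolution-sensitive (~10 %) and would be lubricated away by the thin clinging
film a real plate retains. They shift the *peak-basis* argmax of the sweep to
20 °/s, below the resonance window; the period-averaged basis is robust and is
the recommended one for locating the resonance (`find_resonant_speed(...,
basis="avg")`).

## Wavefront analysis

The bench validation films dyed water at 50 FPS and fits front position
against time within ±2 cm of the CoC; `coc_velocity` reproduces that estimator
(OLS slope with its standard error). In the simulation the bed never fully
dries behind the surge — the laminar film drains on a timescale h²/3ν that
exceeds the rocking period, the model's own analogue of the clinging film seen
on the bench — so `detect_front` tracks a depth contour. The function default
(10 × h_min) suits genuine wet/dry fronts such as dam breaks; for rocking
flows the meaningful front is the travelling bore (≈ 2 mm → 5 mm depth jump at
9 mL), tracked with a contour at ~0.7× the mean fill depth. Only traversals
crossing the CoC are kept by default (`require_coc_crossing=False` for
off-centre validation cases). With 9 mL the simulated median CoC velocity
rises from 0.05 m/s at 20 °/s to 0.10 m/s at 27 °/s and falls to 0.08 m/s at
40 °/s — the qualitative resonance shape — at magnitudes ~35 % below bench
values, consistent with the smeared bores of a shallow-water model. Box
statistics use linear-interpolation quartiles and the 1.5·IQR outlier rule.

## Pipe equivalence

`τ = 4μQ/πR³`, `Q = πR²U`, `Re = ρUd/μ` with laminar validity `Re ≤ 2100`.
Four built-in scenarios cover urethral catheters (12/18 Fr; velocities are
literature-quoted, not recomputed — no pressure-to-flow model is included),
venous catheters (16/24 G via a fixed ISO 9626 inner-diameter lookup),
hemodialysis lines (5 and 9 mm at 200–400 mL/min, computed velocities
17–34 and 5–11 cm/s) and household drinking-water pipes (1.0–2.5 cm). The
household flow is 1 L/min by default: the frequently quoted "1 L/s" is
dimensionally inconsistent with household bulk velocities of 3.4–21 cm/s in
those diameters, but both interpretations are selectable. The equivalence grid
masks on the rocker's peak-shear range by default (most permissive); the
averaged-shear basis is available.

## Thermal model

Two lumped nodes: plate (C ≈ 180 J/K, an ~0.2 kg aluminium holder) and water
(C ≈ 120 J/K, ~28 mL across four wells), coupled at 1.5 W/K, leaking to a
21 °C ambient at 0.8 and 0.2 W/K, driven by a Peltier limited to +40 W heating
/ 25 W cooling with a −9 °C (or ambient − 35 °C) floor. These defaults were
chosen so the closed-loop heating step settles in minutes — the bench-observed
order — and are configurable; they are not fitted to any hardware. The 490 Hz
PWM drive is far above all thermal poles and enters only as its duty-cycle
mean. The PID (default kp = 0.25 /°C, ki = 0.004 /°C·s, kd = 0, 1 s sampling)
measures the in-well (water) sensor, clamps its integral term (anti-windup)
and saturates at ±1 duty; with integral action the steady-state water error is
< 0.05 °C for both 37 °C and 4 °C setpoints. Plant integration is Heun (RK2)
at ≤ 0.25 s substeps under a zero-order-hold duty. The thermistor front end
uses the NTC beta equation (R0 = 10 kΩ, T0 = 298.15 K, B = 3950 K) in a 10 kΩ
divider with a 10-bit ADC; rail counts raise a sensor-fault error.
Spatial gradients inside the plate (bench-observed corner offsets of a few
tenths of a °C) are outside a lumped model.

## Synthetic validation data

The fixtures module generates the three inputs the analysis stages consume,
deterministic under a fixed seed with the generator settings embedded in the
output metadata:

* **Wavefront traces** — constant-velocity position tracks at 50 Hz with
  Gaussian localisation noise, default σ = 0.1 mm. That level is realistic
  sub-pixel dye-front localisation and is the level consistent with reported
  slope standard errors below 0.2 cm/s when a 0.35 m/s front leaves only ~6
  frames inside the ±2 cm window. These traces exercise the estimator, not the
  fluid dynamics: recovery tests certify `coc_velocity`, not the solver.
* **Temperature traces** — closed-loop step responses plus sensor noise
  (default σ = 0.05 °C); `fit_plant` re-simulates the plant open-loop under
  the recorded duty and least-squares-fits chosen parameters (C_water and the
  plate–water conductance recover to within 10 % from a 900 s trace).
* **Shear records** — constructed square/pulse waveforms whose averages,
  peaks and exceedance durations are known arithmetic, for unit-testing the
  reductions.

What passing these tests shows is that each estimator is correct on data
matching its assumptions; real video and thermistor data add systematic
effects (perspective, meniscus contrast, sensor drift) that no synthetic
fixture represents.

## Problem sizes and numerical choices

Production sweeps use 7 speeds × (5 spin-up + 1 recorded) periods at 400
cells (≈ 1 min on one CPU); validation tests use 100–150 cells for rocking
runs and 800–3000 cells for the dam-break and pulse oracles. Quartiles use
linear interpolation; resonance ties break toward the lower speed; degenerate
inputs (empty wells, rail ADC counts, sub-3-point fit windows, fills above
capacity) are rejected with explicit messages rather than clamped.

## Known limitations

* Wall-shear magnitudes carry the parabolic-closure factor (~2) discussed
  above; no transverse (3D) wave physics; no surface tension or contact-angle
  effects, hence no capillary regularisation of contact-line shear spikes.
* Thin-film clinging is represented only implicitly (slow viscous drainage),
  not as a wetting model.
* The pipe map uses the Newtonian water formula throughout — no blood
  rheology, no turbulent shear model (turbulent cells are masked, not
  estimated).
* The thermal plant is qualitative: two nodes with hand-set constants, no
  Peltier device physics beyond asymmetric power limits.
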