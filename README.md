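# rockerflow

Flow, wall-shear and thermal-control simulation for seesaw-rocker biofilm
incubation platforms.

Laboratory rockers grow biofilms in rectangular culture-plate wells by tilting
them periodically, and the wall shear stress this sloshing exerts on the growth
surface is a first-order control on biofilm structure — but it is effectively
impossible to measure at millimetre fluid depths. `rockerflow` is for
microbiologists and instrument builders who need to *choose* rocker settings
(tilt amplitude, rocking speed, fill volume, temperature) to hit a target shear
regime: it simulates the free-surface flow in one well, maps wall shear stress
against rocking speed, translates those stresses to equivalent laminar pipe
flows (catheters, dialysis lines, water pipes), and simulates the Peltier/PID
temperature controller of such a device.

## Models

**Free-surface flow.** The liquid layer (2–5 mm deep in an 8 cm channel) is
modelled with the 1D shallow-water equations in the co-rotating frame of the
tilting plate,

```
h_t + (h u)_x               = 0
(h u)_t + (h u² + ½ g cosθ h²)_x = g sinθ h − 3 ν u / h
```

with tilt angle θ(t) a triangle wave between ±α at rate ω, laminar
(parabolic-profile) bed friction, and wall shear stress τ = 3 μ u / h recorded
along the channel floor. The solver is a well-balanced, positivity-preserving
MUSCL/HLL finite-volume scheme with wetting and drying; it conserves volume to
round-off and holds a tilted lake-at-rest exactly.

**Resonance.** The rocking pumps the slosh hardest when the wavefront returns
in phase with the tilt reversal, at wavefront velocity `ν = ω L / 2α`. For
L = 8 cm and α = 7° this gives 17, 23, 29 cm/s at ω = 30, 40, 50 °/s, and a
shallow-water estimate `ω* = 2α √(g h̄)/L ≈ 27 °/s` for a 5 mL fill.

**Pipe equivalence.** Steady laminar pipe flow exerts `τ = 4 μ Q / (π R³)`
(`Q = π R² U`), valid while `Re = ρ U d / μ ≤ 2100`; the equivalence grid masks
pipe conditions the rocker cannot mimic or that are turbulent.

**Thermal control.** The Peltier-heated sample holder is a two-node lumped
plant (aluminium plate + well water, both leaking to ambient) driven by a
discrete PID controller through a duty-cycle–limited actuator, with an NTC
thermistor (beta equation) front end.

## Worked example

```sh
$ rockerflow pipe --flow-ml-min 200 --diameter-mm 5
{
  "tau_Pa": 0.1875288702046843,
  "U_m_s": 0.16976527263135502,
  "reynolds": 1220.7718853933943,
  "laminar": true
}
```

A hemodialysis bloodline (5 mm inner diameter, 200 mL/min of 37 °C fluid)
carries a bulk velocity of 17 cm/s, stays laminar (Re ≈ 1221 < 2100) and puts
0.19 N/m² of shear on its wall — so a rocker setting whose shear map covers
0.19 N/m² reproduces that environment on a flat coupon.

```python
>>> import rockerflow as rf
>>> [round(rf.resonance_velocity(w, 0.08, 7.0) * 100) for w in (30, 40, 50)]
[17, 23, 29]
>>> rf.rocking_speed_to_rpm(40.0, 7.0)
85.71428571428571
```

The same library call chain produces the shear map: `speed_sweep` runs one
simulation per rocking speed and reduces each to period-averaged and peak
shear per position (`rockerflow sweep` from the shell writes the CSVs). On the
default 5 mL / ±7° configuration the period-averaged map peaks at mid-channel
at ≈ 0.24 N/m² around 30 °/s — the resonance window — while instantaneous
peaks of ≈ 1 N/m² flash at the channel ends; see `docs/methods.md` for what
these magnitudes do and do not represent.

A PID step response:

```python
>>> from rockerflow import ThermalPlant, PIDGains, simulate_step_response
>>> resp = simulate_step_response(ThermalPlant(), PIDGains(), 37.0, 3600.0)
>>> abs(resp.water_c[-1] - 37.0) < 0.05   # integral action: no offset
True
```

The simulated water reaches the 37 °C ± 0.5 °C band in ≈ 10 min from a 21 °C
start, the in-well sensor lagging the platform sensor throughout.

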