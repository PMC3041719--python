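# Methods

## Model structure

The simulator is a lumped-parameter (zero-dimensional) model of the human
circulation built from three element types:

* **Chambers** — time-varying elastance stores. Instantaneous pressure is
  `P = E(t)·max(V − V0, 0)` with `E(t) = e_min + a(t)·(e_max_eff − e_min)`.
  Contractility scales the end-systolic elastance only
  (`e_max_eff = (c/100)·e_max_ref`); the relaxed stiffness `e_min` is a
  passive property. Pressure is floored at zero below the unstressed
  volume `V0`: a model without blood inertia cannot generate suction.
* **Compliant vessels** — linear reservoirs `P = (V − Vu)/C`, floored at
  0 mmHg (no negative transmural pressures in a healthy-system model).
* **Connectors** — ideal diode valves `q = max(ΔP, 0)/R` (strictly
  unidirectional, no regurgitant or stenotic states) and ohmic resistors
  `q = ΔP/R`.

Two fixed topologies are built from these elements. The isolated heart
(IHL) has 5 compartments: a constant-pressure venous source (the CVP
parameter), left atrium, left ventricle, aorta, and a distal arterial bed
draining through the total peripheral resistance into a zero-pressure
sink. The closed loop (CCL) has 10 compartments in a ring — systemic
veins, right atrium and ventricle, pulmonary artery, pulmonary capillary
bed, pulmonary veins, left atrium and ventricle, aorta, arterial bed —
with four valves and the two user-facing resistances placed so that TPR
separates the arterial bed from the systemic veins and the lung
resistance is split evenly across the capillary bed. Which anatomical
segments receive the ten slots is this implementation's choice; the
assignment was made so every user parameter has a natural home.

## Electrical cycle and mechanical triggering

A fixed-rate pacemaker generates each cycle's intervals from quadratics
in the cycle length, `X(rr) = a + b·rr + c·rr²`. The shipped coefficients
are anchored to textbook resting values at rr = 1 s (QT 0.40 s, PR
0.16 s, QRS 0.09 s, P 0.09 s) with the rate dependence concentrated in
QT, fitted through plausible values at the range ends (QT ≈ 0.49 s at
40 min⁻¹, ≈ 0.225 s at 160 min⁻¹, close to Bazett scaling while keeping
PR + QT inside the shortest cycle). The published second-order interval
terms this mechanism emulates are not reproduced verbatim; the
coefficients are configuration, so a user with a preferred interval
formula can substitute their own table, which is validated over the whole
supported rate grid (40–160 min⁻¹, step 1) at load time.

Mechanical activation is a two-phase raised cosine rising over the first
40 % of systole to exactly 1 and falling over the remainder — a smooth,
continuous stand-in for the unpublished activation waveform of the
original. Ventricular systole spans 90 % of QT after the 20 ms
electromechanical delay (the last 10 % of QT is repolarization without
pressure generation); atrial systole lasts twice the P duration starting
at the delay, so the atrial kick completes just after ventricular onset.
The diastolic heart fraction is measured against mechanical systole,
`DHF = 1 − (delay + QT)/RR`, because perfusion time is a mechanical-
diastole quantity; it falls from 0.66 at 40 min⁻¹ to 0.35 at 160 min⁻¹
and is strictly decreasing in rate.

The displayed ECG is assembled from parametric fragments (smooth unimodal
P and T humps, a triphasic QRS of three half-sine lobes) time-scaled to
the interval durations with fixed amplitudes; the output is deliberately
unscaled and used only for timing display, so no recorded human template
library is needed.

## Numerical scheme

The update is the classic recursive scheme at a fixed 1 ms step: all
pressures from current volumes, all flows from current pressures, then an
explicit (forward-Euler) volume update. No adaptive stepping, no implicit
solver, no inertance anywhere. The fastest time constant in the network —
a ventricle ejecting through a semilunar valve into the aortic compliance
— is ≈ 0.7–1.6 ms depending on contractility and compliance, which keeps
the explicit update stable (damped) at 1 ms across the entire limit box;
this is verified by running every corner combination of the parameter
limits. A negative volume, should a custom configuration produce one,
raises an error advising a smaller step rather than silently clamping.

Closed-loop volume conservation needs no correction step: every flow
leaves one compartment and enters another, so the total is conserved to
floating-point rounding (observed drift over 60 000 steps is ~2·10⁻¹¹ ml
against a 1 µl tolerance). Two further numerical checks are part of the
test suite: a single compliant compartment draining through a resistor
must track the closed-form exponential `P0·e^(−t/RC)` within 0.5 % over
one time constant, and halving the step changes the steady-state stroke
volume by < 0.03 % (discretization is not driving the physiology). The
simulator is seed-free; repeat runs are bit-identical.

Heart-rate changes requested mid-run apply at the next cycle boundary so
the interval set and trigger schedule are never torn mid-beat; all other
parameters apply at the next millisecond. A blood-volume change rescales
all compartment volumes proportionally, preserving conservation at the
new total. Each cycle is quantized to `round(RR/Δt)` steps.

Steady state is declared at the first cycle whose end-diastolic volume
(left ventricle; both ventricles in the closed loop) changes by less than
0.1 ml from the previous cycle — EDV is the slowest-settling state of a
compliant loop. At defaults this takes 3 cycles (IHL) and 11 (CCL);
sweeps compute every point from a fresh run to avoid hysteresis.

## Internal constants and calibration

The user-facing surface is seven parameters with published defaults and
hard limits; everything else is fixed in one constants object
(`InternalConstants`). Elastances are textbook-range adult values (LV
e_max 2.5, e_min 0.08; RV 0.6/0.04; atria 0.17/0.12 mmHg/ml; unstressed
volumes 10 ml ventricles, 5 ml atria), as are the vessel compliances
(systemic veins 60, pulmonary veins 15, pulmonary artery 4 ml/mmHg) and
the 20 ms electromechanical delay.

The remaining constants were calibrated once, jointly, so that the
all-default steady state lands at a resting adult operating point
(aortic pressure near 120/80 mmHg, CO 4–6 l/min, EF ≈ 0.55–0.60) and the
model's stated physiological ceilings hold:

* **Inflow (AV) valve resistance 0.015 vs semilunar 0.005
  mmHg·(ml/s)⁻¹.** Giving the mitral/tricuspid inlets a higher effective
  resistance makes passive diastolic filling the rate-limiting process.
  With a uniform low valve resistance, filling completes at every rate
  and the atrial kick's relative value *falls* with heart rate — the
  opposite of the physiology the atria were added to show. With
  rate-limited filling, passive filling completes at rest (the kick adds
  little) but is cut short at high rates (the kick recovers part of the
  deficit), so the atrial contribution rises from ≈ 1.7 % at 70 min⁻¹ to
  ≈ 2.5 % at 160 min⁻¹, under the 10 % ceiling throughout.
* **Venous return resistances 0.003–0.005** keep the atria charged
  quickly so the kick has volume to deliver at short cycle lengths.
* **Systemic venous unstressed volume 3030 ml** sets the stressed volume
  of the 5.2 l loop, and through it venous pressure (~5–7 mmHg), preload
  and the operating point: CCL defaults land at 122/83 mmHg, 5.33 l/min.
  The IHL, whose preload is pinned at the default CVP of 10 mmHg, lands
  at 113/75 mmHg, 5.11 l/min.
* **Distal arterial resistance 0.08 and arterial-bed compliance
  0.3 ml/mmHg** shape the Windkessel: total arterial compliance ≈ 1.8
  ml/mmHg at the default aortic setting gives a ~39 mmHg pulse pressure
  and a diastolic decay constant of ~2 s.

These values are implementation choices, fixed in one place for
reproducibility, and were not changed per-test.

## Experiments and derived geometry

**Atrial contribution.** The closed loop is run to steady state twice —
atria contracting normally, then with their maximal elastance pinned to
the relaxed value — and the relative CO gain is reported. The 10 % bound
is treated as a hard calibration ceiling, enforced by test across the
rate range rather than fitted to an interior value.

**Atrioventricular-plane displacement.** For the animated view's
geometry, the LV is a cylinder `V = π·r²·L` with end-diastolic aspect
ratio L/r = 2.8 (arbitrary length units; the view is schematic). A
fraction f_long = 0.60 of any volume change from EDV is accommodated by
shortening the long axis at the end-diastolic radius — the
atrioventricular plane moving toward the apex — and the remainder by
radial narrowing. By construction the longitudinal share of stroke
volume equals f_long, so the shipped default realizes the documented
"up to 60 %" ceiling exactly; the bound is asserted on the produced
geometry, not on the configuration.

**Summary metrics.** EDV/ESV are per-cycle LV volume extremes over the
last complete cycle, psys/pdia the aortic pressure extremes; SV, CO, EF
and pulse pressure follow by definition (CO = SV·HR exactly). A trace
whose LV volume excursion is below 0.5 ml has no detectable cycle and is
rejected — except in sweeps, where zero preload legitimately produces a
zero-stroke heart and is reported as SV = CO = EF = 0.

## What the model does and does not show

Passing tests demonstrate the mechanisms the model was built to teach —
Frank–Starling, rate-limited filling, Windkessel damping, the bounded
atrial kick — emerging from elastance timing, diode valves and
conservation in a small compartment network. They do not validate against
clinical data: there is no autonomic or humoral regulation (heart rate is
an input, so high-rate behaviour diverges from an in-vivo heart, where
sympathetic drive would raise contractility and venous tone), no blood
inertia (so no pulse-wave propagation, no early-diastolic suction, and
high-energy ejection phases are smoothed), linear ESPVR/EDPVR (real
end-diastolic pressure–volume relations stiffen exponentially; here the
Frank–Starling curve's saturation arises from timing and afterload
interaction instead), healthy valves only, and a pressure floor at zero.
The compartment count (5 and 10) is part of the model's identity, not a
discretization to be refined.

## Problem sizes

Default runs use the 1 ms step throughout: steady-state runs are a few
hundred to a few thousand cycles' worth of steps (well under a second of
wall time each), the conservation check covers a full 60 s (60 000
steps), and sweeps re-run each point from scratch. The entire test suite
simulates a few thousand seconds of model time.
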