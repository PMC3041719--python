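# cardiolab

A deterministic, discrete-time simulator of human cardiovascular mechanics
for teaching and exploration: time-varying elastance heart chambers, diode
valves, Windkessel arterial compliance, and a heart-rate-dependent ECG
timing generator that triggers the mechanical cycle. It is a scriptable
re-creation of the classic interactive "heart lab" used in physiology
courses: students (or scripts) turn a handful of physiological knobs and
watch pressures, volumes and the ECG respond beat by beat.

Two configurations are provided:

* **IHL — isolated heart**: left atrium and ventricle fed by a
  constant-pressure venous source (the preload is a boundary condition),
  ejecting into an open-ended two-stage arterial Windkessel. 5 compartments.
* **CCL — closed circulation loop**: all four chambers plus the systemic
  and pulmonary circulations in a volume-conserving ring. 10 compartments.

## The model

Each chamber follows the Suga–Sagawa elastance formulation

```
E(t) = e_min + a(t) · (e_max_eff − e_min),        a(t) ∈ [0, 1]
P    = E(t) · max(V − V0, 0)
e_max_eff = (contractility / 100) · e_max_ref
```

where `a(t)` is a smooth two-phase activation waveform triggered by the
ECG generator (ventricular onset = PR interval + electromechanical delay).
Vessels are linear compliant reservoirs `P = (V − Vu)/C`; valves are ideal
diodes `q = max(ΔP, 0)/R`; resistors are ohmic. The state is advanced
explicitly at a fixed 1 ms step: pressures from volumes, flows from
pressures, then `V ← V + Δt·(Σq_in − Σq_out)`. In the closed loop every
flow moves volume between two compartments, so total blood volume is
conserved exactly by construction. There are no inertance elements (blood
mass is neglected) and no autonomic reflexes — the heart is paced at a
fixed rate.

The electrical cycle is generated per beat: intervals (P, PR, QRS, QT) are
quadratic functions of the cycle length RR = 60/HR, yielding a diastolic
heart fraction `DHF = 1 − (delay + QT)/RR` that shrinks with rate. The
classic mechanisms are emergent, not scripted: Frank–Starling (stroke
volume rises with filling), rate-limited diastolic filling (stroke volume
falls with heart rate), the Windkessel effect (a stiffer aorta widens the
pulse pressure), and a rate-dependent atrial contribution to cardiac
output bounded at 10 %.

The seven user-facing parameters (with hard limits, rejected when
violated) are: central venous pressure, heart rate, left/right ventricular
contractility, total peripheral resistance, aortic compliance, total lung
resistance and total blood volume. Run `cardiolab info` for the table.

## Worked example

```python
import cardiolab as cl

params = cl.default_parameters("CCL")
model = cl.build(params)
trace, cycle = cl.run_to_steady_state(model, params)
m = cl.cycle_metrics(trace, params.hr)
print(f"steady after {cycle} cycles: SV {m.sv_ml:.1f} ml, "
      f"CO {m.co_ml_min/1000:.2f} l/min, "
      f"BP {m.psys_mmHg:.0f}/{m.pdia_mmHg:.0f} mmHg, EF {m.ef:.2f}")
```

prints

```
steady after 11 cycles: SV 76.1 ml, CO 5.33 l/min, BP 122/83 mmHg, EF 0.57
```

— a resting adult operating point: each beat ejects 76 ml (57 % of the
135 ml end-diastolic volume), 5.3 l/min of output, arterial pressure
122/83 mmHg. The `examples/` directory has one short script per
capability (Frank–Starling sweeps, rate dependence, the ECG generator,
the atrial kick, live mid-run parameter changes, the atrioventricular-
plane geometry), each printing the numbers it computes. The same
functionality is available from the shell:

```bash
cardiolab run --model ccl --duration 30 --out trace.csv
cardiolab sweep --model ihl --param hr --values 40:160:10 --metrics sv_ml,co_ml_min
cardiolab ecg --hr 70
cardiolab atrial --hr 160
```

Everything is seed-free and bit-reproducible: identical inputs give
identical traces.

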