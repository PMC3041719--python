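"""Run the closed double circulation at its defaults and summarize a beat.

The ten-compartment loop (four chambers, systemic + pulmonary circulations)
is advanced in 1 ms steps until the end-diastolic volume settles, then the
last cycle is reduced to the standard hemodynamic numbers.
"""

import cardiolab as cl

params = cl.default_parameters("CCL")
model = cl.build(params)
trace, cycle = cl.run_to_steady_state(model, params)
m = cl.cycle_metrics(trace, params.hr)

print(f"steady state after {cycle} cycles at HR {params.hr:g} min^-1")
print(f"  EDV {m.edv_ml:6.1f} ml   ESV {m.esv_ml:5.1f} ml   SV {m.sv_ml:5.1f} ml")
print(f"  CO  {m.co_ml_min / 1000:6.2f} l/min   EF {m.ef:.2f}")
print(f"  aortic BP {m.psys_mmHg:.0f}/{m.pdia_mmHg:.0f} mmHg "
      f"(pulse pressure {m.pulse_pressure_mmHg:.0f})")
print(f"  diastolic heart fraction {m.dhf:.2f}")
print()
print("EDV−ESV is what one beat ejects; CO = SV × HR is the minute output;")
print("all of it emerges from elastance timing, valves and the loop volume.")
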