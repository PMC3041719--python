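"""Rate-dependent ECG intervals and a synthesized cycle.

The pacemaker's interval generator shortens the electrical cycle
realistically with rate (quadratics in the cycle length RR); the
diastolic heart fraction — the share of each cycle available for filling
and coronary perfusion — shrinks as the rate climbs.
"""

import cardiolab as cl

constants = cl.InternalConstants()
print("HR    RR      P     PR    QRS   QT     DHF")
for hr in (40, 60, 70, 100, 130, 160):
    t = cl.timing_for_rate(float(hr), constants.ecg_coefficients,
                           constants.electromechanical_delay)
    print(f"{hr:3d}  {t.rr:5.3f}  {t.p_dur:5.3f} {t.pr:5.3f} {t.qrs:5.3f} "
          f"{t.qt:5.3f}  {t.dhf:5.2f}")

timing = cl.timing_for_rate(70.0, constants.ecg_coefficients,
                            constants.electromechanical_delay)
ts, amps = cl.synthesize_cycle(timing, constants.dt)
print(f"\none synthesized cycle at 70 min^-1: {len(ts)} samples, "
      f"peak amplitude {amps.max():.2f} au (unscaled)")
print("baseline segments are exactly zero; P, QRS and T fragments are")
print("time-scaled to the interval durations above.")
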