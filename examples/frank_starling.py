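"""Frank-Starling curves: stroke volume versus preload at three inotropies.

Sweeps the central venous pressure of the isolated-heart model at
contractility 50 %, 100 % and 200 %.  More filling pressure means a larger
end-diastolic volume and hence a larger stroke volume; higher inotropy
steepens the whole curve.  Each point is a fresh steady-state run.
"""

import cardiolab as cl

params = cl.default_parameters("IHL")
cvps = [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0]

print("stroke volume (ml) vs CVP (mmHg)")
print("CVP:        " + "".join(f"{c:8.0f}" for c in cvps))
for contractility in (50.0, 100.0, 200.0):
    table = cl.sweep(params.replace(contractility_lv=contractility),
                     "cvp", cvps, metrics_names=("sv_ml",))
    row = "".join(f"{v:8.1f}" for v in table["sv_ml"])
    print(f"c={contractility:3.0f}%:  " + row)

print()
print("Each row rises with preload (the Frank-Starling law) and the rows")
print("are ordered by contractility; at zero preload nothing fills, SV = 0.")
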