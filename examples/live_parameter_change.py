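"""Change a parameter in mid-run, exactly like turning a panel knob.

Doubles the total peripheral resistance after 15 beats without resetting
any state: arterial pressure climbs over the following beats to a new
operating point while the stroke volume falls against the higher afterload.
"""

import cardiolab as cl

params = cl.default_parameters("IHL")
sim = cl.Simulation(cl.build(params), params)

for _ in range(15):
    sim.advance_cycle(record=False)
before = sim.cycle_stats[-1]

sim.set_parameter("tpr", 2.0)   # takes effect at the very next millisecond
for _ in range(15):
    sim.advance_cycle(record=False)
after = sim.cycle_stats[-1]

sv_b = before["edv_lv"] - before["esv_lv"]
sv_a = after["edv_lv"] - after["esv_lv"]
print("                TPR 1.0            TPR 2.0")
print(f"systolic BP   {before['psys']:7.1f} mmHg     {after['psys']:7.1f} mmHg")
print(f"stroke volume {sv_b:7.1f} ml       {sv_a:7.1f} ml")
print()
print("Higher afterload raises pressure and costs stroke volume; heart-rate")
print("changes would instead wait for the next cycle boundary so the")
print("electrical cycle is never torn mid-beat.")
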