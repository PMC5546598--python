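"""Bistability and switching of the genetic toggle switch.

Two genes repress each other; the circuit holds one of two stable
states (R1-high or R2-high, the latter lighting the GFP reporter).
A transient pulse of the inducer enzyme I1 clears R1 and flips the
memory to the GFP-bright state, where it stays after the pulse ends.
"""

import numpy as np

from biospice import Stimulus, build_system, find_stable_states, fixtures, time_course

system = build_system(fixtures()["toggle_switch"])

states = find_stable_states(system, n_starts=32, seed=0)
print(f"stable operating points found: {len(states)}")
for k, x in enumerate(states):
    r1, r2 = x[system.index("R1")], x[system.index("R2")]
    print(f"  state {k}: R1 = {r1:.3f}, R2 = {r2:.3f}")

pulse = Stimulus("I1", "pulse", delay=25.0, length=10.0, height=1.0)
res = time_course(system, [pulse], t_end=200.0, n_points=401)
print(f"before pulse: R1 = {res.series['R1'][0]:.2f}, GFP = {res.series['GFP'][0]:.2f}")
print(f"after pulse:  R1 = {res.series['R1'][-1]:.2f}, GFP = {res.series['GFP'][-1]:.2f}")
print("the pulse moved the circuit to its other stable state"
      if res.series['GFP'][-1] > 5 else "no switch occurred")
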