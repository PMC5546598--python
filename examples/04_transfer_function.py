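"""Small-signal frequency response (Bode data) around an operating point.

A single species produced at rate beta and degraded at rate d is the
biochemical one-pole low-pass filter: a molecule source modulated at
angular frequency w is transmitted with gain 1/sqrt(d^2 + w^2), i.e.
slow modulations pass with gain 1/d and fast ones are averaged out.
"""

import numpy as np

from biospice import Model, Reaction, SpeciesDef, build_system, transfer_function

model = Model(
    species=[SpeciesDef("X", 0.0, 0.5)],
    reactions=[Reaction("C1", products=[("X", 1)], params={"beta": 2.0})],
)
system = build_system(model)

omega = np.array([0.0, 0.05, 0.5, 5.0, 50.0])
res = transfer_function(system, "X", "X", omega)
print("omega   |H|        closed form 1/sqrt(d^2+w^2)")
for w, m in zip(omega, res.series["magnitude"]):
    print(f"{w:6.2f}  {m:9.6f}  {1.0 / np.sqrt(0.25 + w * w):9.6f}")
print("the corner (-3 dB) sits at omega = d = 0.5, the degradation rate")
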