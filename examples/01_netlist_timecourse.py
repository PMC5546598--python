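"""Parse a netlist and integrate its transient.

A substrate S is produced at a constant rate and converted to P by an
enzymatic reaction that its own product inhibits; both species decay.
The printed pair is the long-time operating point the transient relaxes
to: production balances conversion plus decay.
"""

from biospice import build_system, parse_netlist, time_course

NETLIST = """\
* self-inhibited enzymatic conversion
.parameters
alpha 0.5  ; constant substrate production
vmax  1    ; maximal enzymatic rate
km    1    ; Michaelis constant
kp    1    ; product-inhibition half-point
nb    2    ; inhibition cooperativity
.species
S 0 0.1
P 0 0.2
.reactions
C1 {S} {alpha}
X1 {S} {P} 0 'vmax*[S]/(km+[S])*kp^nb/(kp^nb+[P]^nb)'
.simulation
TIMECOURSE 100 201
PLOT {S,P}
"""

model = parse_netlist(NETLIST, name="self_inhibited")
system = build_system(model)
res = time_course(system, None, t_end=100.0, n_points=201)

print(f"species: {', '.join(system.species_order)}")
print(f"S(t=100) = {res.series['S'][-1]:.4f}  (substrate level at the end)")
print(f"P(t=100) = {res.series['P'][-1]:.4f}  (product level at the end)")
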