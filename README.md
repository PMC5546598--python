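# biospice

SPICE-style description and simulation of biochemical reaction networks.

`biospice` is for systems and synthetic biologists (and engineers working at
the biology/electronics interface) who want the workflow that made circuit
simulators ubiquitous: a compact, line-oriented netlist describing the system,
a translator that assembles it into the equivalent dynamical network, and one
engine that runs every standard analysis — operating point, transient with
stimuli, DC sweep, small-signal frequency response and Boolean truth tables.
The package also converts models to and from SBML (Level 2/3 import, Level 3
export) and emits NGSPICE-compatible decks, so the same model text can be
simulated here, in an SBML tool, or in an electronic-circuit simulator
alongside device models.

## The model

The analogy that organises everything: a species' concentration is a node
voltage, a molecule flux is a current.  Each species X with compartment volume
`V_X` and first-order degradation rate `d_X` (a capacitor and a leak resistor)
obeys

```
d[X]/dt = ( Σ_reactions  sign · stoich · v_r([·])  −  d_X·[X] ) / V_X
```

where each reaction with N reactants and M products contributes N+M signed
flux terms ("biological transistors": voltage-controlled current sources),
negative on the reactant side, positive on the product side.  Modifiers
(enzymes, transcription factors, pump regulators) steer rates without carrying
flux.  Built-in rate laws, selected by the first letter of the reaction name:

| letter | mechanism | rate law |
|--------|-----------|----------|
| B | binding         | `k_on·Π[R_k]^n_k − k_off·Π[P_k]^m_k` |
| C | constant source | `β` |
| D | decay           | `d·[X]` |
| E | enzymatic       | `v_max·[E]·[S]/(K_m+[S])` |
| F | diffusion       | `D·([X]_A−[X]_B)` (a 1/D resistor in the circuit) |
| H | Hill reaction   | `v_max·[R]^n/(K^n+[R]^n)` |
| L | translation     | `k_TL·[mRNA]` |
| P | regulated pump  | `v_max·Π_j [M_j]^{n_j}/(K_j^{n_j}+[M_j]^{n_j})` |
| T | transcription   | `k_TR·num/(1+Σ_a([A]/K_A)^{n_A}+Σ_r([R]/K_R)^{n_R})` |
| X | custom          | any quoted expression over `[species]` and parameters |

For T, `num` is the activator sum, or 1 when no activator is declared
(constitutive promoter with pure repression).

A netlist has four dot-keyword sections; parameters may be formulas over
earlier parameters (cycles are rejected):

```
.parameters
vmax 1.2 ; maximal rate
km   vmax/2
.species
S 10 0.1          ; name, initial concentration, degradation rate
P
Enz 0.5
.reactions
E1 {S} {P} {Enz} {vmax,km}
.simulation
TIMECOURSE 50 101
PLOT {S,P}
```

Directives: `FIX`, `PULSE`, `WAVEFORM` (stimuli), `STEADY`, `SWEEP`,
`TIMECOURSE`, `TRANSFUNC`, `TRUTHTABLE` (analyses), `PLOT`, `PLOTALL`
(outputs).  Lines prefixed with `$` are passed through verbatim to the
generated simulator deck.

## Worked example

`examples/02_toggle_bistability.py` builds the genetic toggle switch (two
mutually repressing genes R1/R2, inducer enzymes I1/I2, a GFP reporter
repressed by R1), finds its operating points and flips it with a pulse:

```
stable operating points found: 2
  state 0: R1 = 0.101, R2 = 9.899
  state 1: R1 = 9.899, R2 = 0.101
before pulse: R1 = 10.00, GFP = 0.00
after pulse:  R1 = 0.10, GFP = 9.90
the pulse moved the circuit to its other stable state
```

The two states are the mirror pair of the symmetric bistable
parameterisation (high ≈ `k_TR/d = 10`, low ≈ `10/(1+10²)`); the I1 pulse
enzymatically clears R1, de-represses R2 and GFP, and the circuit stays in
the bright state after the pulse — a set/reset memory element.  The other
examples cover sweeps (`03`), Bode analysis against the closed-form one-pole
response (`04`), truth tables (`05`), SBML round trips (`06`), deck
generation (`07`) and the scaling benchmarks (`08`).

The same runs from the shell:

```
biospice simulate toggle.bb -o results/      # CSV + PNG per PLOT directive
biospice to-sbml toggle.bb -o toggle.xml
biospice from-sbml model.xml -o model.bb     # + import report
biospice to-spice toggle.bb -o toggle.cir
biospice bench grn -n 101 -o grn101.bb
biospice bench pathway -N 20 -M 35 --seed 1 -o pw.bb
```

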