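# Methods

## Model and assumptions

A model is a well-mixed reaction network.  Species are state variables
(concentrations, arbitrary concentration unit); compartments enter only as a
per-species volume that scales accumulation (the capacitor of the circuit
analogy).  Every reaction contributes one signed flux term per reactant and
per product (stoichiometry-weighted), and first-order degradation is a
per-species leak, giving

    d[X]/dt = ( Σ_r sign·stoich·v_r − d_X·[X] ) / V_X .

Deterministic mass-action/Hill kinetics only: no stochastic propensities, no
spatial resolution beyond discrete compartments coupled by linear diffusion
terms, no flux-balance or elementary-mode analyses.  Clamps (`FIX`) are
algebraic: the state is held and its derivative row zeroed, the analog of an
ideal voltage source.

Rate laws are the ten types listed in the README.  Conventions worth
stating:

* **Transcription (T) with no activators.**  The general law is
  `k_TR·Σ_a/(1+Σ_a+Σ_r)` with `Σ_a`, `Σ_r` the activator/repressor Hill
  sums.  An empty activator set would make the numerator identically zero
  and silence the promoter, so it is defined as numerator 1: the law then
  collapses to the standard repressor-only form `k_TR/(1+Σ_r)` used by
  toggle-switch-type circuits.  Simultaneous activators and repressors
  combine through the additive denominator literally; no cross-cooperativity.
* **Enzymatic (E).**  One substrate; the effective enzyme level is the sum
  of the listed modifier concentrations, and 1 when none is listed (enzyme
  folded into `v_max`).  Multiple substrates are rejected.
* **Hill guards.**  `x^n/(K^n+x^n)` is defined as 0 at `x ≤ 0` (so `0^0`
  never arises); the derivative at `x = 0` is one-sided (`1/K` for `n = 1`,
  0 for `n > 1`).

## Netlist format choices

The format is line-oriented with four dot-keyword section headers
(`.parameters`, `.species`, `.reactions`, `.simulation`), `*` full-line and
`;` inline comments, `$`-prefixed verbatim pass-through lines, brace lists
for multi-valued arguments with `0` meaning "absent", an optional integer
stoichiometry prefix (`2*A`) inside species lists, and numeric literals with
scientific notation or SPICE engineering suffixes (`k m u n p f meg g t`).
Identifiers are case-sensitive internally, but names differing only by case
are rejected so that the case-insensitive simulator export stays safe.
Parameter definitions may reference other parameters in any declaration
order; resolution is topological and cycles are reported with their members.
Continuation lines and include files are deliberately unsupported.

## Numerical choices

* **Integrator**: implicit BDF (stiff), `rtol 1e-8`, `atol 1e-12` defaults,
  with an analytic Jacobian assembled from per-reaction partial derivatives
  (central finite differences only inside custom-expression rates, step
  `max(1e-8, 1e-6·|x|)`).  Integration restarts at every stimulus
  discontinuity and timed parameter event.
* **Nonnegativity**: rate laws are evaluated on `max(x, 0)`; the integrator
  may transiently dip a state below zero, which avoids NaNs in
  fractional-power Hill terms without altering the converged trajectory.
* **Steady state**: damped Newton (step halving on the residual norm,
  projection onto the nonnegative orthant) to `‖rhs‖_∞ ≤ 1e-10`, with a
  pseudo-transient fallback (BDF relaxation over geometrically growing
  horizons) when Newton stalls; failures raise with the best residual.
* **Multistart stable-state search**: starts drawn log-uniformly over
  `[1e-3, 1e3] × scale` (scale = max initial concentration or 1) plus the
  model's own initial state; solutions deduplicated at relative distance
  `1e-6`; stability requires every eigenvalue of the free-coordinate
  Jacobian to satisfy `Re λ < −1e-9·‖J‖` (marginal cases count unstable).
  Defaults: 32 starts, seed 0.
* **Transfer function**: linearisation at the operating point;
  `H(jω) = e_outᵀ(jωI−J)⁻¹ e_in` with a unit molecule-source input scaled by
  `1/V_in` (the current-input analog).  A concentration-input convention
  (input row forced) is available behind a flag.
* **Truth table**: `2^k` segments in Gray-code order so exactly one input
  flips per boundary, minimising transient artifacts; outputs are read at
  segment ends; a pulse with frequency 0 is a single shot.
* **DC sweep**: continuation — each grid point warm-starts from the previous
  solution; non-converged points are recorded, not fatal.

## SBML mapping

Import (Level 2/3): kinetic laws become custom-rate reactions with
reaction-local parameters substituted by value and user-defined functions
inlined; compartment sizes become species volumes; boundary/constant species
become clamps; assignment rules are re-evaluated at every rhs call
(topologically ordered, cycles rejected); rate rules add derivative terms
(species targets only); events are supported when time-triggered and
assigning constants to parameters, applied as left-continuous steps with
integrator restarts.  Everything else — algebraic rules, species events,
concentration-dependent triggers, unit definitions, SBML packages — is
recorded in the import report's `dropped` list (or raised in strict mode);
the report partitions the document's constructs so nothing is dropped
silently.

Export (Level 3 Version 1): the kinetic-law formula equals the package's
flux, so the round-tripped system divides by the same compartment volume and
reproduces the derivative field; numeric kinetic constants become global
parameters named `<reaction>_<param>` (no substitution loss on re-import);
dependent netlist parameters become assignment rules; degradation rates
become explicit first-order reactions (SBML has no degradation field);
`FIX`ed species are exported as boundary species; other simulation
directives have no SBML counterpart and are omitted.  Typed rate laws and
their serialised formulas use the same left-folded evaluation order, so a
round trip is bit-identical except for the summation order of the
per-species flux accumulation (relative deviation at machine precision).

## Simulator deck generation

Species → node with capacitor (volume, `ic=` initial concentration) and leak
resistor `1/d`; reactions → behavioral current sources (`B` devices) with the
rate expression over node voltages, one per participant, opposite signs for
reactants and products; diffusion → one resistor `1/D`; constant production →
DC current source; stimuli → DC/PULSE/PWL sources; analyses → `.tran`,
`.dc`, `.ac`, `.op`; plot directives → control-block statements.  Operator
and function spellings are centralised in one dialect table (`^` is emitted
as `pow`, `log10` expanded via `ln` for portability).  Node names are
uppercased species names, prefixed `N_` on collision with reserved words,
with the remapping emitted as comments.  Truth-table inputs are emitted as
periodic pulsed sources in binary-counter order (bit b toggles every 2^b
segments), which covers the same combinations as the engine's Gray-code
schedule.  Generation is deterministic: the same model yields byte-identical
text.  Running an external simulator is out of scope; the package's own
engine is the reference path, and `deck_lint` checks structure (single
analysis, `.end`, no undeclared nodes) statically.

## Synthetic models and fixtures

The fixture structures are fixed by their counts; all kinetic constants
are package choices (documented here, chosen once from standard regimes):

* **Self-inhibited enzymatic loop** (2 species): constant production
  α = 0.5 of S; conversion `v_max·[S]/(K_m+[S])·K_p^{n}/(K_p^{n}+[P]^{n})`
  with `v_max = K_m = K_p = 1`, `n = 2`; decays 0.1 / 0.2.
* **Toggle switch** (7 species, 5 reactions): symmetric repression with
  cooperativity 2 and `k_TR/(d·K) = 10`, which guarantees bistability;
  enzymatic clearance `v_max = K_m = 1` into inert products X1/X2; inducers
  degrade at 0.2 so a pulse is transient.  Initial state R1-high.
* **Repressing-ring networks** (`2n+2` species/reactions): defaults map onto
  the classic scaled operating point of the three-gene oscillator —
  `k_TR = 216`, `K = 1`, `n = 2`, mRNA decay 1, `k_TL = 0.2`, protein decay
  0.2 (scaled maximal production 216, lifetime ratio 5) — which is well
  inside the oscillatory regime; gene 1 starts with one unit of mRNA to
  leave the symmetric invariant manifold.
* **Random pathways**: N-species chain with a constant source (β = 0.1)
  into species 1; the N-th enzymatic reaction has an empty product list and
  acts as the terminal sink, so a steady state exists; reactions N+1..M
  connect uniformly drawn ordered pairs; every enzymatic reaction
  (`v_max = K_m = 1`) is catalysed by a uniformly drawn pathway species; all
  drawn from one seeded generator.
* **Band detector** (4 species): incoherent feed-forward — input half-points
  0.1 (activator branch) and 10 (repressor branch), reporter repressed with
  cooperativity 4 — giving a single interior response maximum.
* **AND gate**: a pump from a clamped reservoir gated by the product of two
  Hill terms (K = 1, n = 2).
* **Penicillin-biosensor biochemistry** (16 species, 14 reactions): five
  species (penicillin, penicilloate, H⁺, HPO₄²⁻, H₂PO₄⁻) in a chamber
  (volume 1) and two sensor-surface compartments (volume 0.01), 10 diffusion
  links (D = 0.05), buffer binding in each compartment, hydrolysis at the
  enzyme-coated surface only.  The buffer kinetics are finite-rate
  (`k_on = 100`, `K_a = 10^−7.2`) so a fast local proton burst outruns
  buffering: the surface pH drops sharply after a diffusion delay and then
  recovers as protons spread into the buffered chamber.  pH is a derived
  output, `−log10([H⁺])`, not a state variable.

What the generators do **not** emulate: molecular noise, transcriptional
bursting, growth/dilution, parameter heterogeneity, and real membrane
electrochemistry.  Passing tests therefore demonstrate correctness of the
translation and numerics on deterministic well-mixed kinetics, not
biological realism of any particular parameter set.

## Problem sizes

The test suite and the acceptance script use sizes chosen to exercise the
scaling claims while keeping a routine run short: oracle comparisons at 100
random states, the ring-network smoke test at 101 genes (204 states,
horizon 100), sweep grids of ~60 points, and generation-only checks at
4999 genes (10000 species).  Cross-simulator comparisons (external SPICE or
SBML tools) and wall-clock benchmarking are intentionally out of scope; the
equivalence oracles and closed-form suites play that role here.

## Known limitations

* Custom-expression Jacobian entries are finite-difference, so extremely
  stiff custom rates may converge slower in Newton than typed ones.
* SBML import targets the core constructs listed above; packages (comp,
  fbc, layout) and unit conversion are unsupported.
* The sweep clamp fixes the input species; sweeping a species that is also
  dynamically produced reads as "held at the grid value", not as a titration
  of its source.
* Truth tables above ~10 inputs are expensive (2^k segments) and capped at
  16.
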