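"""Generate the equivalent electronic-circuit netlist.

Every species becomes a node with a capacitor (compartment volume) and,
if it degrades, a leak resistor of value 1/d; every reaction becomes
behavioral current sources carrying the rate expression (one per
reactant and per product, with opposite signs); diffusion becomes a
single resistor of value 1/D.  The deck is linted for structural
problems before use.
"""

from biospice import deck_lint, fixtures, prune_inert_model, to_spice

model = prune_inert_model(fixtures()["toggle_switch"])
deck = to_spice(model)

print(f"deck lines: {len(deck.lines)}")
print(f"controlled sources: {deck.reaction_source_count} "
      "(the 5 'biological transistors' of the pruned toggle switch)")
print(f"lint findings: {deck_lint(deck)}")
print("--- deck ---")
print(deck.text())
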