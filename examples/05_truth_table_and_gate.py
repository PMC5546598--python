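"""Boolean (truth-table) analysis of a two-input AND gate.

The engine drives every on/off combination of the input molecule
sources, one segment each in Gray-code order, in a single continuous
transient, and reports the output level at the end of each segment.
The pump's product of two Hill terms makes the output high only when
both inputs are present.
"""

from biospice import build_system, fixtures, truth_table

system = build_system(fixtures()["and_gate"])
res, table = truth_table(system, ["A", "B"], on_level=1.0, segment=40.0,
                         outputs=["OUT"])

print("A B | OUT (end of segment)")
for (a, b), values in table:
    print(f"{a} {b} | {values['OUT']:.3f}")
threshold = max(v["OUT"] for _, v in table) / 2
print(f"logic threshold (half of max): {threshold:.3f}")
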