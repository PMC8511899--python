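"""Enzyme-substrate contact table with lyase subsite labels.

Builds a three-sugar mannuronate chain bound over a catalytic triad with
two contacts placed at exact distances (an Arg salt bridge at +1 and a
Tyr hydrogen bond at -1), then enumerates hydrogen bonds and salt
bridges and prints the table in the published column order.
"""

from tunnelflex import default_region_map, interaction_table
from tunnelflex.interactions import records_frame
from tunnelflex.synthetic import make_complex_fixture

st = make_complex_fixture(
    contacts=[
        ("ARG", 215, "NH1", 0, "O6B", 2.9),   # carboxylate neutralizer at +1
        ("TYR", 38, "OH", 1, "O2", 2.8),      # tunnel-roof H-bond at -1
    ]
)
records, counts = interaction_table(st, default_region_map())
print(records_frame(records).to_string(index=False))
print(f"\ncontacts at the catalytic [-1, +1] subsites: {counts}")
print("-> the reducing-end sugar nearest the catalytic triad is subsite +1;")
print("   detected distances equal the construction distances (2.9 / 2.8 A).")
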