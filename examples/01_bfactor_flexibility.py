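"""Flexibility profiling across a pH series of structures.

Builds three synthetic apo models whose 24 substrate-interacting residues
carry a designed 9/12/3 split of high B-factors, then runs the scaled
B-factor analysis and the cross-structure "highest fluctuation"
classification that attributes each residue to the pH where it moves most.
"""

from tunnelflex import default_region_map, mean_bfactor, region_bfactor_report
from tunnelflex.bfactors import highest_fluctuation_classification
from tunnelflex.synthetic import make_bfactor_fixture

rm = default_region_map()
ids = rm.interacting24

# designed winners: first 9 residues fluctuate most at pH 5, next 12 at
# pH 7, last 3 at pH 9 (the split reported for the real apo series)
winners = {"pH5": set(ids[:9]), "pH7": set(ids[9:21]), "pH9": set(ids[21:])}
structures = {
    label: make_bfactor_fixture(
        b_profile=[50.0 if rid in winners[label] else 10.0 for rid in ids],
        residue_ids=ids,
    )
    for label in winners
}

for label, st in structures.items():
    report = region_bfactor_report(st, rm)
    sites = {k: round(v, 2) for k, v in report["sites"].items()}
    print(f"{label}: overall mean B = {mean_bfactor(st):6.2f} A^2, site means {sites}")

assignment, counts, skipped = highest_fluctuation_classification(structures, ids)
print(f"highest-fluctuation counts per structure: {counts} (skipped: {skipped})")
print("-> each residue is claimed by the structure where its scaled B is largest;")
print("   the counts recover the designed 9/12/3 split exactly.")
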