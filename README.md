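# tunnelflex

Comparative structural analysis of pH-series crystal structures of a
polysaccharide-lyase catalytic tunnel, built around the Smlt1473 enzyme
of *Stenotrophomonas maltophilia* — a PL-5-family lyase whose substrate
preference (mannuronate, glucuronate or hyaluronan chains) switches with
pH. The package is aimed at structural biologists who want to turn a set
of coordinate files solved at different pH values into quantitative,
comparable evidence about tunnel flexibility, substrate contacts and
ring stereochemistry.

## What it computes

**B-factor flexibility profiling.** Crystallographic isotropic B-factors
are the flexibility proxy. Because absolute B depends on resolution and
packing, cross-structure comparison uses scaled values
B̃ᵢ = ⟨B⟩ᵢ / ⟨B⟩protein per residue *i*; the atom-count-weighted mean of
B̃ over protein residues is 1 by construction. Site averages (entry,
tunnel, exit of the catalytic tunnel) and a cross-structure argmax
("which pH makes this residue fluctuate most") reproduce the headline
analysis of the pH series.

**Interaction tables.** Hydrogen bonds (heavy-atom cutoff 3.6 Å) and
salt bridges (Arg NE/NH1/NH2 or Lys NZ against carboxylate O, cutoff
4.0 Å) between the enzyme and a bound glycan, each labelled with the
tunnel surface of the protein residue and the lyase subsite of the
sugar: subsites [−1, +1] flank the scissile glycosidic oxygen, with the
reducing end toward the product exit.

**Ring-face classification.** With the least-squares mean plane through
the six pyranose ring atoms and the normal oriented toward the tunnel
roof, a sugar shows its α face when C1, C3 and C5 all lie on the roof
side and its β face when all three lie away; Cremer–Pople puckering is
available as auxiliary output. χ1 rotamer states (g+/t/g−) screen for
side-chain transitions between pH structures.

**Cell metrics.** Triclinic cell volume, Matthews coefficient
V_M = V/(m·Z′·MW) and solvent content (1 − 1.23/V_M)·100.

**Constant-pH Monte Carlo titration.** A fixed-geometry Metropolis
sampler of protonation states with transition free energy

    ΔG = k_B·T·(pH − pKa_ref)·ln 10 + ΔG_elec − ΔG_elec_ref

applied to the protonated microstate, so a null-model site titrates
exactly along Henderson–Hasselbalch, f_prot(pH) = 1/(1+10^(pH−pKa_ref)).
Site–site electrostatic coupling can be plugged in as a state-dependent
energy term.

A synthetic-structure generator (`tunnelflex.synthetic`) builds models
with controlled B profiles, ideal chairs, glycan chains and exact-distance
contacts; its parameters serve as ground truth for the test suite.

## Worked example

```sh
python examples/01_bfactor_flexibility.py
```

prints (three synthetic apo models with a designed 9/12/3 high-B split
over the 24 substrate-interacting residues):

```
pH5: overall mean B =  25.00 A^2, site means {'entry': 50.0, 'tunnel': 27.14, 'exit': 10.0}
pH7: overall mean B =  30.00 A^2, site means {'entry': 10.0, 'tunnel': 32.86, 'exit': 39.09}
pH9: overall mean B =  15.00 A^2, site means {'entry': 10.0, 'tunnel': 10.0, 'exit': 20.91}
highest-fluctuation counts per structure: {'pH5': 9, 'pH7': 12, 'pH9': 3} (skipped: [])
```

The counts mean: 9 of the 24 tunnel residues reach their largest scaled
B in the pH 5 model, 12 in the pH 7 model and 3 in the pH 9 model — the
classification recovers the designed ground truth exactly. The other
examples (`02`–`05`) walk through the interaction table, ring faces,
titration and cell metrics the same way, each printing the numbers it
computes and what they mean.

A thin CLI wraps the same library calls:

```sh
tunnelflex bfactor pH5=a.pdb pH7=b.pdb pH9=c.pdb
tunnelflex interactions complex.pdb
tunnelflex pucker complex.pdb
tunnelflex cell --cell 49.131 94.737 160.499 90 90 90 \
    --space-group "P 21 21 21" --z-prime 2 --mw 34000
tunnelflex titrate --sites sites.tsv --ph-grid 5,6,7,8,9 --seed 1
```

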