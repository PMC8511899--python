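# Methods

## Scope and data model

The package analyzes pH-series crystal structures of the
polysaccharide-lyase Smlt1473, whose catalytic tunnel accepts different
anionic polysaccharides (poly-mannuronate, poly-glucuronate, hyaluronan)
depending on pH. Coordinates are read from fixed-column PDB through
gemmi into a small atom/residue/structure model carrying coordinates,
isotropic B, occupancy and the CRYST1 cell. Author residue numbering is
used everywhere, matching how tunnel residues are cited in the
literature (Y38, R312, …). Alternate locations are resolved by keeping
altloc 'A' or blank; models at 2.2–2.6 Å resolution carry no hydrogens,
so all geometry is heavy-atom based. The backbone atom set is
{N, CA, C, O}.

## Tunnel region map

The 24 substrate-interacting residues are partitioned into entry (6),
tunnel (7) and exit (11) sites, overlaid on the named tunnel surfaces
(roof R1/R2, inner/outer left wall, floor F1/F2, inner/outer right
wall, exit rings i/ii). The partition is data, not code: a YAML override
can move residues, and the invariants (disjoint sites, 24 total) are
re-checked on load. Two curation notes: one published interaction table
places R312 on F1 while the structure-description text and surface
figure place it on F2 — the default keeps F2; membership is by author
number only, with two-copy (Z′ = 2) crystal forms analyzed per chain
and the first protein chain reported by default.

## B-factor statistics

Headline "overall" means include waters and ligands, matching how
refinement tables report overall B; the protein-only mean is kept
separately and used for scaling, because including waters would let
water count bias cross-structure comparison. The scaled value of a
residue is its all-atom mean B divided by the structure's protein-only
mean; the atom-count-weighted average of scaled values over protein
residues is exactly 1, which the tests assert to 1e-9. The
highest-fluctuation classification takes, per residue, the structure
with the maximal scaled value. Scaled B is the default comparison
scale (raw B available by flag) because the apo structures span
noticeably different resolutions. Residues unresolved in a model are
excluded from that structure's competition rather than imputed; ties
break toward the earlier label in supplied order, which makes reports
deterministic. Occupancy weighting is not applied (depositions are near
full occupancy).

## Contact criteria

Distance-only criteria are used — deposited models lack hydrogens, so
donor–H–acceptor angles are unavailable. Defaults: hydrogen bonds at
heavy-atom distance ≤ 3.6 Å between protein polar N/O (side-chain polar
atoms plus backbone N and O) and ligand O/N; salt bridges at ≤ 4.0 Å
between Arg NE/NH1/NH2 or Lys NZ and a carboxylate oxygen. The cutoffs
bracket the longest published table entries (3.6 Å H-bond, 3.5 Å salt
bridge). Histidine ring-nitrogen contacts are classified as hydrogen
bonds, following the published tables, although the ring is ionizable.
Bifurcated contacts appear as separate records; water-mediated bridges
are not enumerated. The donor/acceptor columns follow the tables'
convention of listing the protein atom first even where the chemistry
is ambiguous (hydroxyl–hydroxyl pairs, amide O "donors"). A known
discrepancy in the source material — prose citing the catalytic
tyrosine's two contacts as 2.9/2.7 Å where the table prints 2.8/2.6 Å —
is resolved in favour of the table.

Subsites: sugar units are numbered so that −1 and +1 flank the scissile
glycosidic oxygen. Glycosidic connectivity is inferred from
inter-residue O–C distances < 1.8 Å; the unit whose ring centroid is
nearest the catalytic-machinery centroid (N167/H168/Y222) is +1, the
reducing end (free anomeric C1) is oriented toward the product exit,
units on the reducing side of +1 take +2, +3, … and the nonreducing
side −1, −2, …. Contacts to the scissile oxygen itself are labelled as
bridging [−1, +1]. Branched or disconnected ligand sets are rejected
rather than guessed at.

## Ring faces and rotamers

The ring plane is the least-squares plane through C1, C2, C3, C4, C5,
O5 (SVD); signed displacements are measured along the normal oriented
toward a reference point. The face is α when the C1/C3/C5 displacements
are all positive, β when all negative, indeterminate otherwise, with a
0.05 Å dead band so flattened puckers are not noise-classified and a
hard error when the reference point is within 0.1 Å of the plane. The
published face language is figure-relative ("above the plane"); the
package fixes it as "toward the tunnel roof", defaulting the reference
to the Y38+Y39 lid-loop centroid, which reproduces the +1 = α / −1 = β
pattern of the trapped mannuronate complexes. The convention for the
−2 subsite labels has not been independently verified against deposited
coordinates and the reference point is therefore exposed as an option.
Cremer–Pople (Q, θ, φ) is computed as auxiliary output only. χ1 is the
N–CA–CB–γ dihedral in the standard biochemical sign convention, binned
g+ = (0°, 120°], t = (120°, 180°] ∪ (−180°, −120°], g− = (−120°, 0°];
transition screening compares every structure's bin against the first
(lowest-pH) label, with unresolved side chains flagged as changed.

## Cell metrics

Triclinic volume uses the closed form
abc·√(1 − cos²α − cos²β − cos²γ + 2cosαcosβcosγ), cross-checked against
the metric-tensor route in gemmi to 1e-6 relative. Space-group
multiplicities for the five groups of the study's crystal forms are a
built-in table (P2₁2₁2₁:4, P1:1, P2₁2₁2:4, C222₁:8, P3₁21:6); other
symbols resolve through gemmi's operation count. Solvent content uses
Matthews' classic constant 1.23; published solvent percentages derive
from slightly different constants and molecular weights, so agreement
is asserted at ±1 percentage point rather than reverse-engineering the
original constant.

## Constant-pH Monte Carlo

The titration engine samples binary protonation states by Metropolis
Monte Carlo at fixed geometry. The pH-dependent term is
ΔG = k_B·T·(pH − pKa_ref)·ln 10 + ΔG_elec − ΔG_elec_ref with
k_B = 1.9872×10⁻³ kcal/(mol·K) and T defaulting to 300 K. The sign
convention is fixed by the reference-compound limit: ΔG is carried by
the protonated microstate, which is the unique reading under which a
null-model site (ΔG_elec = ΔG_elec_ref) titrates along
Henderson–Hasselbalch, f_prot = 1/(1+10^(pH−pKa_ref)), and a constant
offset of +k_B·T·ln 10 lowers the apparent pKa by exactly one unit.
The implementation is energy-based — a total free energy over the
protonation microstate whose single-flip differences reproduce the
per-site equation — so state-dependent site–site coupling terms can be
plugged in while detailed balance continues to hold; the tests verify
the stationary distribution of a coupled two-site system against
Boltzmann weights by chi-square. Proposals pick a site uniformly,
accept with min(1, e^(−ΔG/kBT)) (ΔG = 0 always accepted); burn-in
defaults to 10% of attempts and the state is recorded once per sweep
thereafter. Each pH grid point restarts from the all-protonated state
with an independently spawned RNG stream, so runs are bit-reproducible
per seed and grid points are independent. pKa estimates come from a
Hill-form fit of the protonated-fraction curve, which must bracket 0.5.
No conformational propagation occurs between MC steps and no
generalized-Born electrostatics is computed: the engine is a
desk-scale sampler with a pluggable electrostatic hook, not a molecular
dynamics method, and no quantitative pKa predictions for the enzyme's
own residues are claimed.

## Synthetic fixtures and what passing tests show

The generator emulates exactly the features the analyses assume:
per-residue B profiles applied exactly (jitter touches coordinates
only), ideal chairs built on a hexagonal template with ±0.25 Å
out-of-plane displacements, (4←1)-linked glycan chains with a free
anomeric hydroxyl marking the reducing end, and donor atoms placed at
requested distances to 0.001 Å along directions chosen to avoid
unintended short contacts. Fixtures are serialized to PDB text and
re-parsed before use, so every test exercises the real I/O path at
format precision (3 decimals on coordinates, 2 on B); REMARK records
carry the generating parameters. These fixtures have ideal geometry
and no crystallographic noise, disorder, alternate conformations or
solvent networks: passing tests demonstrate the correctness of the
statistics and geometry on known ground truth, not the fidelity of any
particular deposited model. The published-number reproduction tests,
which do run the same code paths on the six deposited entries, require
those coordinate files to be supplied locally under `data/deposited/`.

## Problem sizes

Test and acceptance runs use fixtures of tens of residues, single
glycan chains of 1–4 sugars, titration grids of ~9 pH points with
1–6×10⁴ MC attempts per point, and 10⁵-proposal acceptance-rate
counts; the full suite completes in well under a minute on one CPU.
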