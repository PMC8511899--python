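"""B-factor flexibility profiling across a pH series of crystal structures.

Crystallographic isotropic B-factors are used as a proxy for local
flexibility.  Because absolute B scales with resolution and crystal
packing, cross-structure comparison works on *scaled* values: each
residue's all-atom mean B divided by the structure's protein-only mean B.
The atom-count-weighted mean of the scaled values over protein residues
is exactly 1 by construction.

The headline whole-molecule average includes waters and ligands (this is
the refinement-table "overall B"); the protein-only mean is used for
scaling to avoid water-count bias.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .regions import RegionMap, SITE_ORDER, parse_residue_id
from .structure import SelectionSpec, Structure, BACKBONE_ATOMS, select

__all__ = [
    "BfactorProfile",
    "mean_bfactor",
    "scaled_profile",
    "region_bfactor_report",
    "highest_fluctuation_classification",
]


@dataclasses.dataclass
class ResidueB:
    all_atom: float
    backbone: float | None
    sidechain: float | None
    n_atoms: int


@dataclasses.dataclass
class BfactorProfile:
    per_residue: dict[tuple[str, int], ResidueB]   # (chain, seq) -> means
    overall_mean: float                            # every atom incl. waters/ligands
    protein_mean: float
    scaled: dict[tuple[str, int], float]           # residue all-atom mean / protein mean

    def weighted_scaled_mean(self) -> float:
        """Atom-count-weighted mean of scaled values over protein residues (== 1)."""
        num = sum(self.scaled[key] * self.per_residue[key].n_atoms for key in self.scaled)
        den = sum(self.per_residue[key].n_atoms for key in self.scaled)
        return num / den


def mean_bfactor(structure: Structure, selection: SelectionSpec | None = None) -> float:
    """Unweighted arithmetic mean of atomic B over the selected atoms."""
    refs = select(structure, selection) if selection is not None else select(structure)
    if not refs:
        raise ValueError("mean_bfactor: empty selection")
    return float(np.mean([ref.atom.bfactor for ref in refs]))


def scaled_profile(structure: Structure, chain: str | None = None) -> BfactorProfile:
    """Per-residue raw and scaled B statistics for the protein residues.

    ``chain`` restricts the per-residue profile (the overall and protein
    means always use the whole model so scaling is per-structure).
    """
    all_b = [atom.bfactor for _, atom in structure.iter_atoms()]
    if not all_b:
        raise ValueError("structure has no atoms")
    protein_b = [
        atom.bfactor
        for res, atom in structure.iter_atoms()
        if res.is_protein
    ]
    if not protein_b:
        raise ValueError("structure has no protein atoms")
    protein_mean = float(np.mean(protein_b))
    if protein_mean == 0:
        raise ValueError("protein mean B is zero; cannot scale")

    per_residue: dict[tuple[str, int], ResidueB] = {}
    scaled: dict[tuple[str, int], float] = {}
    for res in structure.iter_residues():
        if not res.is_protein:
            continue
        if chain is not None and res.chain_id != chain:
            continue
        bvals = np.array([a.bfactor for a in res.atoms])
        bb = [a.bfactor for a in res.atoms if a.name in BACKBONE_ATOMS]
        sc = [a.bfactor for a in res.atoms if a.name not in BACKBONE_ATOMS]
        key = (res.chain_id, res.seq_id)
        per_residue[key] = ResidueB(
            all_atom=float(bvals.mean()),
            backbone=float(np.mean(bb)) if bb else None,
            sidechain=float(np.mean(sc)) if sc else None,
            n_atoms=len(res.atoms),
        )
        scaled[key] = per_residue[key].all_atom / protein_mean
    return BfactorProfile(
        per_residue=per_residue,
        overall_mean=float(np.mean(all_b)),
        protein_mean=protein_mean,
        scaled=scaled,
    )


def _site_residues_present(
    structure: Structure, region_map: RegionMap, site: str, chain: str
) -> tuple[list[tuple[str, int]], list[str]]:
    present: list[tuple[str, int]] = []
    missing: list[str] = []
    for rid in region_map.sites[site]:
        _, num = parse_residue_id(rid)
        if structure.residue(chain, num) is not None:
            present.append((rid, num))
        else:
            missing.append(rid)
    return present, missing


def region_bfactor_report(
    structure: Structure,
    region_map: RegionMap,
    chain: str | None = None,
) -> dict:
    """Site-level mean B plus per-residue raw/scaled values.

    Residues absent from the model (unresolved density) are reported under
    ``missing`` and excluded from the site averages; a site with every
    member missing has mean ``None``.
    """
    if chain is None:
        chains = structure.protein_chains()
        if not chains:
            raise ValueError("structure has no protein chain")
        chain = chains[0]
    profile = scaled_profile(structure, chain=chain)
    report: dict = {"chain": chain, "sites": {}, "missing": {}, "residues": []}
    for site in SITE_ORDER:
        present, missing = _site_residues_present(structure, region_map, site, chain)
        report["missing"][site] = missing
        site_b: list[float] = []
        for rid, num in present:
            res = structure.residue(chain, num)
            site_b.extend(a.bfactor for a in res.atoms)
            key = (chain, num)
            report["residues"].append(
                {
                    "site": site,
                    "residue": rid,
                    "raw_B": profile.per_residue[key].all_atom,
                    "scaled_B": profile.scaled[key],
                }
            )
        report["sites"][site] = float(np.mean(site_b)) if site_b else None
    return report


def highest_fluctuation_classification(
    structures: dict[str, Structure],
    residue_set: tuple[str, ...],
    chain: str | None = None,
    scaled: bool = True,
) -> tuple[dict[str, str], dict[str, int], list[str]]:
    """Attribute each residue to the structure where it fluctuates most.

    For each residue id the (scaled, by default) all-atom B is compared
    across the labeled structures and the label with the maximum wins;
    ties break in favour of the earlier label, in supplied order.
    Residues unresolved in a given model do not compete there; residues
    absent everywhere are skipped and returned in the third element.

    Returns ``(assignment, counts_per_label, skipped)``; counts sum to the
    number of residues classified.
    """
    if len(structures) < 1:
        raise ValueError("need at least one labeled structure")
    profiles: dict[str, BfactorProfile] = {}
    chains: dict[str, str] = {}
    for label, st in structures.items():
        ch = chain if chain is not None else st.protein_chains()[0]
        chains[label] = ch
        profiles[label] = scaled_profile(st, chain=ch)

    assignment: dict[str, str] = {}
    counts: dict[str, int] = {label: 0 for label in structures}
    skipped: list[str] = []
    for rid in residue_set:
        _, num = parse_residue_id(rid)
        best_label, best_val = None, -np.inf
        for label in structures:
            key = (chains[label], num)
            prof = profiles[label]
            if key not in prof.per_residue:
                continue
            val = prof.scaled[key] if scaled else prof.per_residue[key].all_atom
            if val > best_val:
                best_label, best_val = label, val
        if best_label is None:
            skipped.append(rid)
            continue
        assignment[rid] = best_label
        counts[best_label] += 1
    return assignment, counts, skipped


def classification_frame(
    structures: dict[str, Structure],
    region_map: RegionMap,
    chain: str | None = None,
    scaled: bool = True,
) -> pd.DataFrame:
    """Long-form table (structure_label, site, residue, raw_B, scaled_B, is_max)."""
    assignment, _, _ = highest_fluctuation_classification(
        structures, region_map.interacting24, chain=chain, scaled=scaled
    )
    rows = []
    for label, st in structures.items():
        report = region_bfactor_report(st, region_map, chain=chain)
        for entry in report["residues"]:
            rows.append(
                {
                    "structure_label": label,
                    "site": entry["site"],
                    "residue": entry["residue"],
                    "raw_B": entry["raw_B"],
                    "scaled_B": entry["scaled_B"],
                    "is_max": assignment.get(entry["residue"]) == label,
                }
            )
    return pd.DataFrame(rows)
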