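"""Synthetic structure fixtures with known ground truth.

Generates small coordinate models that emulate the statistical and
geometric features the analysis modules assume — per-atom B-factor
profiles, ideal pyranose chairs with a known face, glycan chains with
glycosidic connectivity near a catalytic triad, and donor-acceptor
contacts at prescribed distances — so every stage is testable without
touching deposited data.  The construction parameters are the oracle:
tests compare detected quantities against what the generator placed.

Every fixture is serialized to PDB text and re-parsed before being
returned, so consumers exercise the real parser path and values carry
format precision (3 decimals on coordinates, 2 on B).  REMARK records
carry the generating parameters.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .structure import Atom, Residue, Structure, parse_structure, write_structure

__all__ = [
    "place_atom",
    "make_bfactor_fixture",
    "make_ring_fixture",
    "make_glycan_chain",
    "make_contact_fixture",
    "make_complex_fixture",
    "make_sidechain_residue",
]

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

_RING_RADIUS = 1.435       # in-plane radius giving ~1.52 A ring bonds
_RING_Z = 0.25             # chair out-of-plane displacement
_RING_NAMES = ("C1", "C2", "C3", "C4", "C5", "O5")

#: out-of-plane sign pattern per conformer for (C1, C2, C3, C4, C5, O5)
_CONFORMER_SIGNS = {
    "4C1": (+1, -1, +1, -1, +1, -1),
    "1C4": (-1, +1, -1, +1, -1, +1),
    "planar": (0, 0, 0, 0, 0, 0),
    # twisted non-chair: C1/C3/C5 displacements of mixed sign
    "half_chair": (+1, 0, -1, 0, +1, -1),
}

_CARBOXYLATE_SUGARS = {"BEM", "BDP", "LGU"}


def _roundtrip(structure: Structure, remarks: Sequence[str]) -> Structure:
    text = write_structure(structure, remarks=remarks)
    return parse_structure(text)


def place_atom(p1, p2, p3, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate atom placement (natural extension reference frame).

    Returns the position of atom 4 given the three preceding atoms, the
    3-4 bond length, the 2-3-4 angle and the 1-2-3-4 torsion.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    b2 = p3 - p2
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(p2 - p1, b2)
    n = n / np.linalg.norm(n)
    m = np.cross(n, b2n)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return p3 + d[0] * b2n + d[1] * m + d[2] * n


# ---------------------------------------------------------------------------
# B-factor fixtures

def make_bfactor_fixture(
    b_profile: float | Sequence[float],
    residue_ids: Sequence[str] | None = None,
    n_residues: int | None = None,
    chain_id: str = "A",
    start_seq: int = 22,
    jitter: float = 0.0,
    seed: int = 0,
    waters: tuple[int, float] | None = None,
) -> Structure:
    """Chain with exact per-residue B values.

    ``b_profile`` is a constant or one value per residue, applied to every
    atom of that residue.  ``residue_ids`` (e.g. ``["Y38", "R312"]``)
    names and numbers the residues so region maps apply; otherwise a
    poly-alanine chain numbered from ``start_seq`` is built.  ``waters``
    adds ``(count, B)`` water molecules so whole-molecule and
    protein-only averages differ.  ``jitter`` adds seeded Gaussian noise
    to coordinates only — B values are always exact.
    """
    if residue_ids is not None:
        specs = [(THREE_LETTER[rid[0]], int(rid[1:])) for rid in residue_ids]
    else:
        if n_residues is None:
            raise ValueError("give residue_ids or n_residues")
        specs = [("ALA", start_seq + i) for i in range(n_residues)]
    n = len(specs)
    if np.isscalar(b_profile):
        b_values = [float(b_profile)] * n
    else:
        b_values = [float(b) for b in b_profile]
        if len(b_values) != n:
            raise ValueError("b_profile length must match residue count")

    rng = np.random.default_rng(seed)
    residues = []
    for i, ((name, seq), b) in enumerate(zip(specs, b_values)):
        base = np.array([3.8 * i, 0.0, 0.0])
        offsets = {
            "N": (0.0, 0.0, 0.0),
            "CA": (1.46, 0.0, 0.0),
            "C": (2.0, 1.3, 0.0),
            "O": (1.6, 2.4, 0.2),
            "CB": (1.9, -0.8, 1.2),
        }
        atoms = []
        for atom_name, off in offsets.items():
            if atom_name == "CB" and name == "GLY":
                continue
            coord = base + np.array(off)
            if jitter > 0:
                coord = coord + rng.normal(scale=jitter, size=3)
            atoms.append(
                Atom(
                    name=atom_name,
                    element=atom_name[0],
                    coord=coord,
                    bfactor=b,
                )
            )
        residues.append(Residue(chain_id=chain_id, seq_id=seq, name=name, atoms=atoms))

    chains = {chain_id: residues}
    if waters is not None:
        count, wb = waters
        wres = []
        for k in range(count):
            wres.append(
                Residue(
                    chain_id="S",
                    seq_id=401 + k,
                    name="HOH",
                    atoms=[
                        Atom(
                            name="O",
                            element="O",
                            coord=np.array([3.8 * k, 8.0, 8.0]),
                            bfactor=float(wb),
                            is_hetero=True,
                        )
                    ],
                )
            )
        chains["S"] = wres
    structure = Structure(chains=chains)
    return _roundtrip(
        structure,
        remarks=[
            f"SYNTHETIC BFACTOR FIXTURE seed={seed} jitter={jitter}",
            f"B PROFILE {' '.join(f'{b:.2f}' for b in b_values)}",
        ],
    )


# ---------------------------------------------------------------------------
# sugar ring fixtures

def _ring_coords(conformer: str, rotation_deg: float = 0.0) -> np.ndarray:
    if conformer not in _CONFORMER_SIGNS:
        raise ValueError(
            f"unknown conformer {conformer!r}; choose from {sorted(_CONFORMER_SIGNS)}"
        )
    signs = _CONFORMER_SIGNS[conformer]
    coords = []
    for k, s in enumerate(signs):
        theta = math.radians(60.0 * k + rotation_deg)
        coords.append(
            [
                _RING_RADIUS * math.cos(theta),
                _RING_RADIUS * math.sin(theta),
                _RING_Z * s,
            ]
        )
    return np.array(coords)


def _radial(k: int, rotation_deg: float) -> np.ndarray:
    theta = math.radians(60.0 * k + rotation_deg)
    return np.array([math.cos(theta), math.sin(theta), 0.0])


def _sugar_residue(
    conformer: str,
    resname: str,
    seq_id: int,
    chain_id: str = "B",
    origin: np.ndarray | None = None,
    rotation_deg: float = 0.0,
    omit: Sequence[str] = (),
    bfactor: float = 20.0,
) -> Residue:
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    ring = _ring_coords(conformer, rotation_deg) + origin
    atoms = [
        Atom(name=n, element=n[0], coord=c, bfactor=bfactor, is_hetero=True)
        for n, c in zip(_RING_NAMES, ring)
    ]

    def add(name, coord):
        if name not in omit:
            atoms.append(
                Atom(name=name, element=name[0], coord=coord, bfactor=bfactor,
                     is_hetero=True)
            )

    # equatorial hydroxyls, radially outward from their ring carbon
    add("O1", ring[0] + 1.43 * _radial(0, rotation_deg))
    add("O2", ring[1] + 1.43 * _radial(1, rotation_deg))
    add("O3", ring[2] + 1.43 * _radial(2, rotation_deg))
    add("O4", ring[3] + 1.43 * _radial(3, rotation_deg))
    if resname in _CARBOXYLATE_SUGARS:
        c6 = ring[4] + 1.52 * _radial(4, rotation_deg)
        add("C6", c6)
        add("O6A", c6 + 1.25 * _radial(4, rotation_deg - 50.0))
        add("O6B", c6 + 1.25 * _radial(4, rotation_deg + 50.0))
    else:  # amino sugar: exocyclic hydroxymethyl O6 and acetamido N2
        c6 = ring[4] + 1.52 * _radial(4, rotation_deg)
        add("C6", c6)
        add("O6", c6 + 1.43 * _radial(4, rotation_deg - 40.0))
        add("N2", ring[1] + 1.45 * (_radial(1, rotation_deg) + np.array([0, 0, 0.8]))
            / np.linalg.norm(_radial(1, rotation_deg) + np.array([0, 0, 0.8])))
    return Residue(chain_id=chain_id, seq_id=seq_id, name=resname, atoms=atoms)


def make_ring_fixture(
    conformer: str = "4C1",
    resname: str = "BEM",
    seq_id: int = 601,
    bfactor: float = 20.0,
) -> Structure:
    """Single ideal-geometry pyranose residue.

    In the 4C1 fixture C1, C3 and C5 sit at +z of the ring mean plane
    (displacement ~ +0.25 A), so a reference point above the ring sees
    the alpha face; the 1C4 fixture is its mirror image.
    """
    res = _sugar_residue(conformer, resname, seq_id, bfactor=bfactor)
    structure = Structure(chains={"B": [res]})
    return _roundtrip(
        structure, remarks=[f"SYNTHETIC RING FIXTURE conformer={conformer}"]
    )


def make_glycan_chain(
    n_sugars: int = 3,
    resname: str = "BEM",
    start_seq: int = 601,
    seq_step: int = 100,
    conformer: str = "4C1",
    spacing: float = 5.2,
    chain_id: str = "B",
) -> list[Residue]:
    """Linear (4<-1)-linked glycan with the reducing end first.

    Ring i+1's anomeric C1 is bonded through a glycosidic oxygen to ring
    i's C4 position; the bridging O is an atom of ring i (named O4), and
    ring 0 keeps a free anomeric O1 — it is the reducing end.
    """
    residues = []
    for i in range(n_sugars):
        origin = np.array([spacing * i, 0.0, 0.0])
        omit = ["O4"]          # replaced by the bridging O below (except last)
        if i > 0:
            omit.append("O1")  # anomeric position is glycosidically bonded
        res = _sugar_residue(
            conformer, resname, start_seq + seq_step * i,
            chain_id=chain_id, origin=origin, rotation_deg=180.0, omit=omit,
        )
        residues.append(res)
    # bridging oxygens, equidistant (1.43 A) from C4(i) and C1(i+1)
    for i in range(n_sugars - 1):
        c4 = residues[i].atom("C4").coord
        c1 = residues[i + 1].atom("C1").coord
        mid = 0.5 * (c4 + c1)
        axis = c1 - c4
        half = 0.5 * np.linalg.norm(axis)
        if half >= 1.43:
            raise ValueError("sugar spacing too large for a glycosidic bond")
        perp = np.cross(axis, np.array([0.0, 0.0, 1.0]))
        perp = perp / np.linalg.norm(perp)
        bridge = mid + math.sqrt(1.43**2 - half**2) * perp
        residues[i].atoms.append(
            Atom(name="O4", element="O", coord=bridge, bfactor=20.0, is_hetero=True)
        )
    # restore terminal O4 hydroxyl on the nonreducing end
    last = residues[-1]
    c4 = last.atom("C4").coord
    last.atoms.append(
        Atom(name="O4", element="O", coord=c4 + 1.43 * _radial(3, 180.0)
             + np.array([0.0, 0.0, 0.6]), bfactor=20.0, is_hetero=True)
    )
    return residues


def make_sidechain_residue(
    resname: str,
    seq_id: int,
    chi1_deg: float,
    chain_id: str = "A",
    origin: np.ndarray | None = None,
) -> Residue:
    """Residue with N, CA, CB and a gamma atom at an exact chi1 torsion."""
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    n = origin + np.array([1.458, 0.0, 0.0])
    ca = origin.copy()
    cb = place_atom(n + np.array([0.0, 1.0, 0.0]), n, ca, 1.53, 110.0, 120.0)
    gamma_name = {"SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1",
                  "ILE": "CG1"}.get(resname, "CG")
    gamma = place_atom(n, ca, cb, 1.52, 112.0, chi1_deg)
    atoms = [
        Atom(name="N", element="N", coord=n, bfactor=15.0),
        Atom(name="CA", element="C", coord=ca, bfactor=15.0),
        Atom(name="CB", element="C", coord=cb, bfactor=15.0),
        Atom(name=gamma_name, element=gamma_name[0], coord=gamma, bfactor=15.0),
    ]
    return Residue(chain_id=chain_id, seq_id=seq_id, name=resname, atoms=atoms)


def make_contact_fixture(
    contacts: Sequence[tuple[str, str, str, float]],
    sugar_resname: str = "BEM",
    conformer: str = "4C1",
    seed: int = 0,
) -> Structure:
    """One sugar plus one minimal protein residue per requested contact.

    Each contact is ``(protein_resname, donor_atom, sugar_atom, distance)``;
    the donor atom is placed exactly at the given heavy-atom distance from
    the named sugar atom, pointing away from the sugar atom's bonded
    parent so no unintended short contact arises.  Distances are realized
    to 0.001 A before format rounding.  Two atoms closer than 1.0 A —
    a geometric clash — raise an error.
    """
    sugar = _sugar_residue(conformer, sugar_resname, 601)
    parent = {
        "O1": "C1", "O2": "C2", "O3": "C3", "O4": "C4",
        "O6A": "C6", "O6B": "C6", "O6": "C6", "O5": "C1", "N2": "C2",
    }
    protein_residues = []
    for idx, (resname, donor_atom, sugar_atom, distance) in enumerate(contacts):
        if distance <= 1.5:
            raise ValueError("contact distances must exceed 1.5 A")
        target = sugar.atom(sugar_atom)
        if target is None:
            raise ValueError(f"sugar has no atom {sugar_atom!r}")
        anchor = sugar.atom(parent.get(sugar_atom, "C1"))
        direction = target.coord - anchor.coord
        direction = direction / np.linalg.norm(direction)
        donor = target.coord + distance * direction
        ca = target.coord + (distance + 7.0) * direction
        n = ca + np.array([0.0, 0.0, 1.45])
        protein_residues.append(
            Residue(
                chain_id="A",
                seq_id=100 + idx,
                name=resname,
                atoms=[
                    Atom(name="N", element="N", coord=n, bfactor=15.0),
                    Atom(name="CA", element="C", coord=ca, bfactor=15.0),
                    Atom(name=donor_atom, element=donor_atom[0], coord=donor,
                         bfactor=15.0),
                ],
            )
        )
    structure = Structure(chains={"A": protein_residues, "B": [sugar]})
    coords = [a.coord for _, a in structure.iter_atoms()]
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.linalg.norm(coords[i] - coords[j]) < 1.0:
                raise ValueError("geometric clash: two atoms closer than 1.0 A")
    remarks = ["SYNTHETIC CONTACT FIXTURE seed=%d" % seed] + [
        f"CONTACT {r}:{d} -> {sugar_resname}601:{s} {dist:.3f} A"
        for r, d, s, dist in contacts
    ]
    return _roundtrip(structure, remarks)


def make_complex_fixture(
    n_sugars: int = 3,
    contacts: Sequence[tuple[str, int, str, int, str, float]] = (),
    triad_offset: np.ndarray | None = None,
) -> Structure:
    """Glycan chain plus a catalytic triad, for subsite and table tests.

    The triad (ASN167, HIS168, TYR222 stand-ins) is centred near the
    reducing-end sugar, which therefore takes subsite +1 with its chain
    partners at -1, -2, ... — the topology of the pH-trapped complexes.
    ``contacts`` entries ``(resname, seq_id, donor_atom, sugar_index,
    sugar_atom, distance)`` add exact protein-sugar contacts.
    """
    sugars = make_glycan_chain(n_sugars)
    offset = np.array([0.0, -8.0, 4.0]) if triad_offset is None else np.asarray(triad_offset)
    ring0 = np.mean([sugars[0].atom(n).coord for n in _RING_NAMES], axis=0)
    contact_seqs = {seq for _, seq, *_ in contacts}
    triad = []
    for resname, seq, shift in (
        ("ASN", 167, (0.0, 0.0, 0.0)),
        ("HIS", 168, (2.5, 0.0, 0.5)),
        ("TYR", 222, (-2.5, 0.0, 0.5)),
    ):
        if seq in contact_seqs:   # a requested contact stands in for this residue
            continue
        base = ring0 + offset + np.array(shift)
        triad.append(
            Residue(
                chain_id="A", seq_id=seq, name=resname,
                atoms=[
                    Atom(name="N", element="N", coord=base, bfactor=15.0),
                    Atom(name="CA", element="C", coord=base + np.array([1.2, 0.6, 0.0]),
                         bfactor=15.0),
                ],
            )
        )
    parent = {
        "O1": "C1", "O2": "C2", "O3": "C3", "O4": "C4",
        "O6A": "C6", "O6B": "C6", "O6": "C6",
    }
    extra = []
    for resname, seq, donor_atom, sugar_index, sugar_atom, distance in contacts:
        target = sugars[sugar_index].atom(sugar_atom)
        if target is None:
            raise ValueError(f"sugar {sugar_index} has no atom {sugar_atom!r}")
        anchor = sugars[sugar_index].atom(parent.get(sugar_atom, "C1"))
        direction = target.coord - anchor.coord
        direction = direction / np.linalg.norm(direction)
        donor = target.coord + distance * direction
        ca = target.coord + (distance + 7.0) * direction
        extra.append(
            Residue(
                chain_id="A", seq_id=seq, name=resname,
                atoms=[
                    Atom(name="N", element="N", coord=ca + np.array([0, 0, 1.45]),
                         bfactor=15.0),
                    Atom(name="CA", element="C", coord=ca, bfactor=15.0),
                    Atom(name=donor_atom, element=donor_atom[0], coord=donor,
                         bfactor=15.0),
                ],
            )
        )
    protein = sorted(triad + extra, key=lambda r: r.seq_id)
    structure = Structure(chains={"A": protein, "B": sugars})
    coords = [a.coord for _, a in structure.iter_atoms()]
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.linalg.norm(coords[i] - coords[j]) < 1.0:
                raise ValueError(
                    "geometric clash: a requested contact collides with the glycan"
                )
    return _roundtrip(
        structure,
        remarks=[f"SYNTHETIC COMPLEX FIXTURE n_sugars={n_sugars}"],
    )
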