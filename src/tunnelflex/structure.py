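"""Macromolecular structure data model and PDB coordinate I/O.

The model is deliberately small: atoms carry coordinates, isotropic
B-factors and occupancies; residues use *author* numbering throughout
(the literature on this enzyme family cites residues as Y38, R312 etc.
in author numbering); the structure keeps the crystallographic cell and
space group from CRYST1.  Parsing is delegated to :mod:`gemmi`; writing
is a plain fixed-column serializer of this data model.

Deposited models in the resolution range handled here (2.2-2.6 A) carry
no hydrogens, so all downstream geometry is heavy-atom based.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SelectionSpec",
    "AtomRef",
    "ParseError",
    "parse_structure",
    "write_structure",
    "select",
    "BACKBONE_ATOMS",
    "WATER_NAMES",
    "SUGAR_COMPONENTS",
]

#: Backbone heavy-atom set, the --CA-(C=O)-N-- unit.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Chemical component codes of the uronate/amino sugars handled here:
#: beta-D-mannuronate, beta-D-glucuronate, N-acetyl-glucosamine,
#: alpha-L-guluronate.
SUGAR_COMPONENTS = frozenset({"BEM", "BDP", "NAG", "LGU"})


class ParseError(ValueError):
    """Raised for malformed or empty coordinate input."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray          # (3,) Cartesian, Angstrom
    bfactor: float             # isotropic B, A^2
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name}: B-factor must be >= 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy must be in [0, 1]")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_id: int                # author numbering
    name: str                  # 3-letter code
    atoms: list[Atom] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"residue {self.name}{self.seq_id}: duplicate atom names {dup}"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_sugar(self) -> bool:
        return self.name in SUGAR_COMPONENTS

    @property
    def is_protein(self) -> bool:
        return not any(a.is_hetero for a in self.atoms) and not self.is_water

    def centroid(self) -> np.ndarray:
        return np.mean([a.coord for a in self.atoms], axis=0)


@dataclasses.dataclass
class Structure:
    chains: dict[str, list[Residue]] = dataclasses.field(default_factory=dict)
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    z_prime: int = 1

    def __post_init__(self) -> None:
        if self.cell is not None:
            a, b, c, al, be, ga = self.cell
            if min(a, b, c) <= 0:
                raise ValueError("cell lengths must be > 0")
            if not all(0.0 < x < 180.0 for x in (al, be, ga)):
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.z_prime < 1:
            raise ValueError("z_prime must be >= 1")

    def iter_residues(self) -> Iterator[Residue]:
        for chain_id in self.chains:
            yield from self.chains[chain_id]

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.iter_residues():
            for atom in res.atoms:
                yield res, atom

    def residue(self, chain_id: str, seq_id: int) -> Residue | None:
        for res in self.chains.get(chain_id, ()):
            if res.seq_id == seq_id:
                return res
        return None

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def protein_chains(self) -> list[str]:
        out = []
        for cid, residues in self.chains.items():
            if any(r.is_protein for r in residues):
                out.append(cid)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigid-body transformed copy (coordinates only)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_chains: dict[str, list[Residue]] = {}
        for cid, residues in self.chains.items():
            new_chains[cid] = [
                Residue(
                    chain_id=r.chain_id,
                    seq_id=r.seq_id,
                    name=r.name,
                    atoms=[
                        Atom(
                            name=a.name,
                            element=a.element,
                            coord=rotation @ a.coord + translation,
                            bfactor=a.bfactor,
                            occupancy=a.occupancy,
                            is_hetero=a.is_hetero,
                        )
                        for a in r.atoms
                    ],
                )
                for r in residues
            ]
        return Structure(
            chains=new_chains,
            cell=self.cell,
            space_group=self.space_group,
            z_prime=self.z_prime,
        )


# ---------------------------------------------------------------------------
# parsing

def _validate_fixed_columns(text: str) -> None:
    # gemmi is forgiving about unparsable numeric fields; enforce the
    # fixed-column contract here so bad records fail loudly with a line number.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: truncated ATOM/HETATM record")
        fields = [
            ("serial", line[6:11]),
            ("resseq", line[22:26]),
            ("x", line[30:38]),
            ("y", line[38:46]),
            ("z", line[46:54]),
        ]
        if len(line) >= 60:
            fields.append(("occupancy", line[54:60]))
        if len(line) >= 66:
            fields.append(("bfactor", line[60:66]))
        for field, raw in fields:
            raw = raw.strip()
            if not raw:
                continue
            try:
                float(raw)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed {field} field {raw!r}"
                ) from None


def parse_structure(text: str) -> Structure:
    """Parse fixed-column PDB content into a :class:`Structure`.

    Alternate locations are resolved by keeping altloc 'A' or blank and
    dropping the rest (deposition-standard choice).  CRYST1, when present,
    populates the cell and space group.
    """
    if not any(
        line.startswith(("ATOM  ", "HETATM")) for line in text.splitlines()
    ):
        raise ParseError("input contains no ATOM or HETATM record")
    _validate_fixed_columns(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise ParseError(str(exc)) from exc

    chains: dict[str, list[Residue]] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            atoms: list[Atom] = []
            for at in res:
                if at.altloc not in ("", "\x00", "A"):
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        bfactor=at.b_iso,
                        occupancy=min(1.0, at.occ),
                        is_hetero=(res.het_flag == "H"),
                    )
                )
            if not atoms:
                continue
            chains.setdefault(chain.name, []).append(
                Residue(
                    chain_id=chain.name,
                    seq_id=res.seqid.num,
                    name=res.name,
                    atoms=atoms,
                )
            )

    cell = None
    space_group = None
    if st.cell.is_crystal():
        cell = (
            st.cell.a, st.cell.b, st.cell.c,
            st.cell.alpha, st.cell.beta, st.cell.gamma,
        )
        space_group = st.spacegroup_hm or None
    return Structure(chains=chains, cell=cell, space_group=space_group)


# ---------------------------------------------------------------------------
# writing

def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} exceeds PDB column width")
    if len(name) == 4:
        return name
    # single-letter elements start in column 14
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure: Structure, remarks: Sequence[str] = ()) -> str:
    """Serialize to fixed-column PDB (ATOM/HETATM, CRYST1, TER, END).

    Coordinates keep 3 decimals and B-factors 2 decimals, the format
    precision; re-parsing the output reproduces them exactly at that
    precision.
    """
    lines: list[str] = []
    for remark in remarks:
        lines.append(f"REMARK 300 {remark}"[:80])
    if structure.cell is not None:
        a, b, c, al, be, ga = structure.cell
        sg = (structure.space_group or "P 1")[:11]
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}"
        )
    serial = 0
    for chain_id, residues in structure.chains.items():
        last_polymer: Residue | None = None
        for res in residues:
            if len(res.name) > 3:
                raise ValueError(f"residue name {res.name!r} exceeds PDB column width")
            record = "HETATM" if any(a.is_hetero for a in res.atoms) else "ATOM  "
            for atom in res.atoms:
                serial += 1
                name = _format_atom_name(atom.name, atom.element)
                x, y, z = atom.coord
                lines.append(
                    f"{record}{serial:5d} {name}"
                    f"{'':1s}{res.name:>3s} {chain_id:1s}{res.seq_id:4d}{'':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
            if record == "ATOM  ":
                last_polymer = res
        if last_polymer is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last_polymer.name:>3s} "
                f"{chain_id:1s}{last_polymer.seq_id:4d}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# selection

@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """Conjunctive atom filter: every given clause must match."""

    chain: str | None = None
    seq_range: tuple[int, int] | None = None     # inclusive
    seq_ids: frozenset[int] | None = None
    res_names: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    hetero: bool | None = None
    exclude_water: bool = False

    def __post_init__(self) -> None:
        if self.seq_range is not None:
            lo, hi = self.seq_range
            if lo > hi:
                raise ValueError(f"empty seq_range {self.seq_range}")

    def matches(self, res: Residue, atom: Atom) -> bool:
        if self.chain is not None and res.chain_id != self.chain:
            return False
        if self.seq_range is not None and not (
            self.seq_range[0] <= res.seq_id <= self.seq_range[1]
        ):
            return False
        if self.seq_ids is not None and res.seq_id not in self.seq_ids:
            return False
        if self.res_names is not None and res.name not in self.res_names:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.hetero is not None and atom.is_hetero != self.hetero:
            return False
        if self.exclude_water and res.is_water:
            return False
        return True


@dataclasses.dataclass(frozen=True)
class AtomRef:
    chain_id: str
    residue: Residue
    atom: Atom


def select(structure: Structure, spec: SelectionSpec | None = None, **clauses) -> list[AtomRef]:
    """Return atoms matching all filter clauses, in (chain, seq, name) order.

    An unknown chain yields an empty selection rather than an error.
    Clauses may be given as a :class:`SelectionSpec` or as keyword
    arguments with the same names (lists are accepted for set fields).
    """
    if spec is None:
        for key in ("seq_ids", "res_names", "atom_names"):
            if key in clauses and clauses[key] is not None:
                clauses[key] = frozenset(clauses[key])
        spec = SelectionSpec(**clauses)
    elif clauses:
        raise ValueError("pass either a SelectionSpec or keyword clauses, not both")
    hits = [
        AtomRef(res.chain_id, res, atom)
        for res, atom in structure.iter_atoms()
        if spec.matches(res, atom)
    ]
    hits.sort(key=lambda ref: (ref.chain_id, ref.residue.seq_id, ref.atom.name))
    return hits
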