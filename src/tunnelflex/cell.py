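"""Unit-cell volume, Matthews coefficient and solvent content.

V_M (Matthews coefficient) is the crystal volume per Dalton of
macromolecule, V / (m * Z' * MW) with m the space-group multiplicity
(asymmetric units per cell) and Z' the number of molecules per
asymmetric unit.  Solvent content follows Matthews' classic estimate
(1 - 1.23 / V_M) * 100 with the protein partial specific volume constant
1.23; refinement programs use slightly different constants, so published
solvent percentages agree with this one to about one percentage point.
"""

from __future__ import annotations

import math
import warnings

import gemmi

__all__ = [
    "unit_cell_volume",
    "matthews",
    "solvent_content",
    "space_group_multiplicity",
    "SPACE_GROUP_MULTIPLICITY",
    "CRYSTAL_FORMS",
]

#: built-in multiplicities for the space groups of the crystal forms
#: analyzed here; arbitrary Hermann-Mauguin symbols go through gemmi
SPACE_GROUP_MULTIPLICITY = {
    "P 21 21 21": 4,
    "P 1": 1,
    "P 21 21 2": 4,
    "C 2 2 21": 8,
    "P 31 2 1": 6,
}

#: deposited crystal forms of the Smlt1473 pH series: label -> cell
#: (a, b, c, alpha, beta, gamma), space group, molecules per asu
CRYSTAL_FORMS = {
    "pH5_apo": {
        "pdb_id": "7FHX",
        "cell": (49.131, 94.737, 160.499, 90.0, 90.0, 90.0),
        "space_group": "P 21 21 21",
        "z_prime": 2,
    },
    "pH7_apo": {
        "pdb_id": "7FHY",
        "cell": (43.652, 57.943, 67.569, 71.14, 89.71, 73.79),
        "space_group": "P 1",
        "z_prime": 2,
    },
    "pH9_apo": {
        "pdb_id": "7FHZ",
        "cell": (47.983, 160.579, 46.942, 90.0, 90.0, 90.0),
        "space_group": "P 21 21 2",
        "z_prime": 1,
    },
    "pH5_tetraManA": {
        "pdb_id": "7FI0",
        "cell": (105.757, 160.662, 48.160, 90.0, 90.0, 90.0),
        "space_group": "C 2 2 21",
        "z_prime": 1,
    },
    "pH7_hexaManA": {
        "pdb_id": "7FI1",
        "cell": (48.139, 160.228, 46.878, 90.0, 90.0, 90.0),
        "space_group": "P 21 21 2",
        "z_prime": 1,
    },
    "pH5_tetraHA_H168A": {
        "pdb_id": "7FI2",
        "cell": (75.564, 75.564, 112.360, 90.0, 90.0, 120.0),
        "space_group": "P 31 2 1",
        "z_prime": 1,
    },
}

#: Matthews' protein partial-specific-volume constant (Da per A^3 inverse)
MATTHEWS_CONSTANT = 1.23


def unit_cell_volume(
    a: float, b: float, c: float, alpha: float, beta: float, gamma: float
) -> float:
    """Triclinic cell volume in A^3 (lengths in A, angles in degrees)."""
    if min(a, b, c) <= 0:
        raise ValueError("cell lengths must be > 0")
    if not all(0.0 < x < 180.0 for x in (alpha, beta, gamma)):
        raise ValueError("cell angles must lie in (0, 180) degrees")
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0:
        raise ValueError("angle combination does not define a valid cell")
    return a * b * c * math.sqrt(disc)


def space_group_multiplicity(symbol: str) -> int:
    """Asymmetric units per cell for a Hermann-Mauguin symbol."""
    key = symbol.strip()
    if key in SPACE_GROUP_MULTIPLICITY:
        return SPACE_GROUP_MULTIPLICITY[key]
    sg = gemmi.find_spacegroup_by_name(key)
    if sg is None:
        raise ValueError(f"unknown space group symbol {symbol!r}")
    return len(sg.operations())


def matthews(
    volume: float, sg_multiplicity: int, z_prime: int, mw: float
) -> float:
    """Matthews coefficient V_M = V / (m * Z' * MW) in A^3/Da."""
    if min(volume, sg_multiplicity, z_prime, mw) <= 0:
        raise ValueError("all Matthews inputs must be > 0")
    return volume / (sg_multiplicity * z_prime * mw)


def solvent_content(vm: float) -> float:
    """Solvent percentage (1 - 1.23 / V_M) * 100, clipped to [0, 100]."""
    if vm <= 0:
        raise ValueError("V_M must be > 0")
    if vm <= MATTHEWS_CONSTANT:
        warnings.warn(
            f"V_M {vm:.2f} <= {MATTHEWS_CONSTANT}: implied solvent content <= 0%",
            stacklevel=2,
        )
        return 0.0
    return (1.0 - MATTHEWS_CONSTANT / vm) * 100.0
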