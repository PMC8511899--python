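"""Pyranose ring-face classification, puckering and side-chain rotamers.

A pyranose presents one of two faces to a binding surface.  With the
least-squares mean plane through the six ring atoms (C1..C5, O5) and the
plane normal oriented toward a reference point (by default the tunnel
roof), the ring shows its *alpha* face when C1, C3 and C5 all lie on the
reference side of the plane and its *beta* face when all three lie on
the far side; mixed signs (planar or half-chair puckers) are
indeterminate.  In an ideal chair the two atom triads sit ~0.25 A on
either side of the plane.

Side-chain chi1 (N-CA-CB-gamma) torsions are binned into the three
staggered rotamer wells so that pH-series structures can be screened for
rotameric transitions of substrate-binding residues.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .structure import Residue, Structure

__all__ = [
    "RING_ATOM_ORDER",
    "RingConformation",
    "TorsionState",
    "ring_mean_plane",
    "ring_conformation",
    "classify_face",
    "cremer_pople",
    "dihedral",
    "chi1",
    "rotamer_transitions",
    "roof_reference_point",
]

RING_ATOM_ORDER = ("C1", "C2", "C3", "C4", "C5", "O5")

#: gamma heavy atom candidates per residue type, in lookup order
_GAMMA_ATOMS = ("CG", "CG1", "OG", "OG1", "SG")


@dataclasses.dataclass
class RingConformation:
    ring_atoms: np.ndarray        # (6,3) in RING_ATOM_ORDER
    centroid: np.ndarray
    normal: np.ndarray            # unit vector
    displacements: np.ndarray     # signed distance of each ring atom from plane
    face: str                     # 'alpha' | 'beta' | 'indeterminate'


@dataclasses.dataclass
class TorsionState:
    residue_id: str
    chi1: float | None            # degrees in (-180, 180], None if unresolved
    rotamer_bin: str              # 'g+' | 't' | 'g-' | 'unresolved'


def ring_mean_plane(ring_atoms: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares plane through six ring atoms.

    Returns (centroid, unit normal, signed displacements along the
    normal).  The displacements of a least-squares plane sum to zero.
    """
    coords = np.asarray(ring_atoms, dtype=float)
    if coords.shape != (6, 3):
        raise ValueError("ring_mean_plane expects a (6, 3) coordinate array")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered)
    # degenerate geometry: coincident or collinear atoms leave <2
    # independent in-plane directions
    if s[1] < 1e-6:
        raise ValueError("ring atoms are collinear or coincident; no plane defined")
    normal = vt[2]
    displacements = centered @ normal
    return centroid, normal, displacements


def classify_face(
    ring_atoms: np.ndarray,
    reference_point: np.ndarray,
    min_displacement: float = 0.05,
) -> str:
    """'alpha' if C1, C3, C5 all point toward the reference, 'beta' if away.

    ``min_displacement`` (A) is the magnitude below which an atom is
    considered in-plane, making flattened puckers indeterminate rather
    than noise-classified.
    """
    centroid, normal, disp = ring_mean_plane(ring_atoms)
    ref = np.asarray(reference_point, dtype=float)
    side = float(np.dot(ref - centroid, normal))
    if abs(side) < 0.1:
        raise ValueError("reference point lies within 0.1 A of the ring plane")
    if side < 0:
        normal, disp = -normal, -disp
    triad = disp[[0, 2, 4]]   # C1, C3, C5
    if np.all(triad > min_displacement):
        return "alpha"
    if np.all(triad < -min_displacement):
        return "beta"
    return "indeterminate"


def ring_conformation(
    residue: Residue, reference_point: np.ndarray
) -> RingConformation:
    """Face-classified ring conformation of one pyranose residue."""
    coords = []
    for name in RING_ATOM_ORDER:
        atom = residue.atom(name)
        if atom is None:
            raise ValueError(
                f"residue {residue.name}{residue.seq_id} lacks ring atom {name}"
            )
        coords.append(atom.coord)
    coords = np.array(coords)
    centroid, normal, disp = ring_mean_plane(coords)
    face = classify_face(coords, reference_point)
    return RingConformation(
        ring_atoms=coords,
        centroid=centroid,
        normal=normal,
        displacements=disp,
        face=face,
    )


def roof_reference_point(
    structure: Structure, chain: str | None = None, seq_ids: tuple[int, int] = (38, 39)
) -> np.ndarray:
    """Centroid of the lid-loop residues forming the tunnel roof.

    The face convention used throughout is "toward the tunnel roof": the
    default reference point is the centroid of the two aromatic lid-loop
    residues (author numbers 38 and 39 in this enzyme).
    """
    if chain is None:
        chain = structure.protein_chains()[0]
    coords = []
    for seq in seq_ids:
        res = structure.residue(chain, seq)
        if res is not None:
            coords.extend(a.coord for a in res.atoms)
    if not coords:
        raise ValueError(f"roof residues {seq_ids} absent from chain {chain}")
    return np.mean(coords, axis=0)


def cremer_pople(ring_atoms: np.ndarray) -> tuple[float, float, float]:
    """Cremer-Pople puckering (Q, theta_deg, phi_deg) for a six-membered ring.

    Auxiliary output only; face calls use the mean-plane sign rule.
    """
    coords = np.asarray(ring_atoms, dtype=float)
    if coords.shape != (6, 3):
        raise ValueError("cremer_pople expects a (6, 3) coordinate array")
    center = coords.mean(axis=0)
    r = coords - center
    # mean plane defined by the CP construction
    rp = sum(r[j] * math.sin(2 * math.pi * j / 6) for j in range(6))
    rpp = sum(r[j] * math.cos(2 * math.pi * j / 6) for j in range(6))
    n = np.cross(rp, rpp)
    n = n / np.linalg.norm(n)
    z = r @ n
    q2c = math.sqrt(2 / 6) * sum(z[j] * math.cos(4 * math.pi * j / 6) for j in range(6))
    q2s = -math.sqrt(2 / 6) * sum(z[j] * math.sin(4 * math.pi * j / 6) for j in range(6))
    q3 = math.sqrt(1 / 6) * sum(z[j] * (-1) ** j for j in range(6))
    q2 = math.hypot(q2c, q2s)
    Q = math.hypot(q2, q3)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(q2s, q2c)) % 360.0
    return Q, theta, phi


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def rotamer_bin(chi: float) -> str:
    """Staggered-well bin: g+ = (0,120], t = (120,180] u (-180,-120], g- = (-120,0]."""
    if 0.0 < chi <= 120.0:
        return "g+"
    if -120.0 < chi <= 0.0:
        return "g-"
    return "t"


def chi1(residue: Residue) -> TorsionState:
    """chi1 torsion (N-CA-CB-gamma heavy atom), binned into rotamer wells.

    Residues lacking any of the four atoms (glycine, or density gaps in
    the model) come back 'unresolved' rather than raising.
    """
    rid = f"{residue.name}{residue.seq_id}"
    n, ca, cb = (residue.atom(x) for x in ("N", "CA", "CB"))
    gamma = None
    for name in _GAMMA_ATOMS:
        gamma = residue.atom(name)
        if gamma is not None:
            break
    if any(a is None for a in (n, ca, cb, gamma)):
        return TorsionState(residue_id=rid, chi1=None, rotamer_bin="unresolved")
    ang = dihedral(n.coord, ca.coord, cb.coord, gamma.coord)
    return TorsionState(residue_id=rid, chi1=ang, rotamer_bin=rotamer_bin(ang))


def rotamer_transitions(
    structures: dict[str, Structure],
    seq_ids: tuple[int, ...],
    chain: str | None = None,
) -> dict[int, dict]:
    """Per-residue chi1 bins across labeled structures, flagged vs the first.

    The first label is the reference (conventionally the lowest-pH
    structure).  ``changed`` is True when a structure's bin differs from
    the reference bin or is unresolved.  Residues absent from every
    structure are skipped.
    """
    labels = list(structures)
    if len(labels) < 2:
        raise ValueError("need at least two labeled structures")
    out: dict[int, dict] = {}
    for seq in seq_ids:
        states: dict[str, TorsionState] = {}
        for label, st in structures.items():
            ch = chain if chain is not None else st.protein_chains()[0]
            res = st.residue(ch, seq)
            if res is None:
                states[label] = TorsionState(f"?{seq}", None, "unresolved")
            else:
                states[label] = chi1(res)
        if all(s.rotamer_bin == "unresolved" for s in states.values()):
            continue
        ref_bin = states[labels[0]].rotamer_bin
        out[seq] = {
            "bins": {label: s.rotamer_bin for label, s in states.items()},
            "chi1": {label: s.chi1 for label, s in states.items()},
            "changed": {
                label: (s.rotamer_bin != ref_bin or s.rotamer_bin == "unresolved")
                for label, s in states.items()
                if label != labels[0]
            },
        }
    return out
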