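"""Curated catalytic-tunnel nomenclature for the Smlt1473 lyase.

The substrate-binding tunnel of this (alpha/alpha)-toroid polysaccharide
lyase is described by named surfaces: at the entry face two concentric
annuli subdivided into roof (R1/R2), outer/inner left wall (oLW/iLW),
floor (F1/F2) and outer/inner right wall (oRW/iRW); at the exit face two
rings of interacting surfaces (i and ii).  Overlaid on the surfaces is a
three-way partition of the 24 substrate-interacting residues into entry,
tunnel and exit *sites* (6 + 7 + 11), plus the catalytic residues.

The partition is stored as data, not code, so any disagreement with a
user's own curation can be fixed via a YAML override file.  Membership is
by author residue number (a single chain is assumed per crystallographic
copy; two-copy models are analyzed per chain).
"""

from __future__ import annotations

import dataclasses
import re

import yaml

__all__ = ["RegionMap", "default_region_map", "load_region_map", "parse_residue_id"]

_RESID_RE = re.compile(r"^([A-Z])(\d+)$")


def parse_residue_id(rid: str) -> tuple[str, int]:
    """Split an identifier like 'Y38' into (one-letter code, author number)."""
    m = _RESID_RE.match(rid.strip())
    if not m:
        raise ValueError(f"malformed residue identifier {rid!r} (expected e.g. 'Y38')")
    return m.group(1), int(m.group(2))


_DEFAULT_SURFACES: dict[str, tuple[str, ...]] = {
    # entry face, outer annulus (between circles 1 and 2)
    "R1": ("S45", "V46", "I47", "P49", "Q217"),
    "oLW": ("Q53", "D57", "A60", "P61"),
    "F1": ("R64", "Y65", "D68", "R71", "D74"),
    "oRW": ("L278", "P279", "L280", "Q281", "R305", "G306", "P307", "F308", "H309"),
    # entry face, inner annulus (between circles 2 and 3)
    "R2": ("Y39", "R218"),
    "iLW": ("Y38", "Q52", "N55", "K56"),
    "F2": ("D63", "R312"),
    "iRW": ("W171", "H221", "Y222", "Y225"),
    # exit face rings
    "exit_ring_i": ("Y115", "R215", "N166"),
    "exit_ring_ii": ("K42", "K162", "R163", "N109", "N110", "D111"),
}

_DEFAULT_SITES: dict[str, tuple[str, ...]] = {
    "entry": ("Q52", "K56", "D63", "R218", "H221", "R312"),
    "tunnel": ("Y38", "Y39", "N55", "W119", "W171", "Y222", "Y225"),
    "exit": (
        "K42", "N110", "Q112", "Y115", "K162", "R163",
        "N166", "N167", "H168", "E212", "R215",
    ),
    # catalytic machinery plus the innermost-circle surface residue Q112
    "catalytic": ("N167", "H168", "Y222", "Q112"),
}

SITE_ORDER = ("entry", "tunnel", "exit")


@dataclasses.dataclass(frozen=True)
class RegionMap:
    """Named residue sets partitioning the catalytic tunnel."""

    surfaces: dict[str, tuple[str, ...]]
    sites: dict[str, tuple[str, ...]]

    @property
    def interacting24(self) -> tuple[str, ...]:
        """The substrate-interacting residues, entry then tunnel then exit."""
        out: list[str] = []
        for site in SITE_ORDER:
            out.extend(self.sites[site])
        return tuple(out)

    def site_of(self, rid: str) -> str | None:
        for site in SITE_ORDER:
            if rid in self.sites[site]:
                return site
        return None

    def site_of_number(self, seq_id: int) -> str | None:
        for site in SITE_ORDER:
            for rid in self.sites[site]:
                if parse_residue_id(rid)[1] == seq_id:
                    return site
        return None

    def surface_of_number(self, seq_id: int) -> str | None:
        for surface, rids in self.surfaces.items():
            for rid in rids:
                if parse_residue_id(rid)[1] == seq_id:
                    return surface
        return None

    def site_numbers(self, site: str) -> tuple[int, ...]:
        return tuple(parse_residue_id(rid)[1] for rid in self.sites[site])

    def validate(self) -> None:
        for name, rids in list(self.surfaces.items()) + list(self.sites.items()):
            for rid in rids:
                parse_residue_id(rid)
        seen: dict[str, str] = {}
        for site in SITE_ORDER:
            for rid in self.sites[site]:
                if rid in seen:
                    raise ValueError(
                        f"residue {rid} assigned to both {seen[rid]} and {site} sites"
                    )
                seen[rid] = site
        n = len(seen)
        if n != 24:
            raise ValueError(
                f"entry/tunnel/exit sites must cover exactly 24 residues, got {n}"
            )
        # substrate-interacting surface residues must sit in exactly one
        # site set; site disjointness above already enforces "at most one",
        # so only a membership count per surface residue remains to check
        for surface, rids in self.surfaces.items():
            for rid in rids:
                hits = sum(rid in self.sites[s] for s in SITE_ORDER)
                if hits > 1:
                    raise ValueError(f"surface {surface} residue {rid} in {hits} sites")


def default_region_map() -> RegionMap:
    """The built-in tunnel map (entry 6, tunnel 7, exit 11 residues).

    Note: one published interaction table labels R312 as an F1 (outer
    floor) residue while the structure-description text and the surface
    figure place it on F2; the default keeps the F2 assignment.
    """
    rm = RegionMap(surfaces=dict(_DEFAULT_SURFACES), sites=dict(_DEFAULT_SITES))
    rm.validate()
    return rm


def load_region_map(config_text: str) -> RegionMap:
    """Build a RegionMap from YAML, overriding defaults entry-by-entry.

    The config maps region names (surface or site names) to residue-id
    lists; unknown names become new surfaces.  Invariants are re-checked,
    so moving a residue into a second site set is an error.
    """
    data = yaml.safe_load(config_text) or {}
    if not isinstance(data, dict):
        raise ValueError("region-map config must be a mapping of name -> residue list")
    surfaces = dict(_DEFAULT_SURFACES)
    sites = dict(_DEFAULT_SITES)
    for name, rids in data.items():
        if rids is None:
            rids = []
        if isinstance(rids, str):
            rids = rids.split()
        rids = tuple(str(r) for r in rids)
        if name in sites:
            sites[name] = rids
        else:
            surfaces[name] = rids
    rm = RegionMap(surfaces=surfaces, sites=sites)
    rm.validate()
    return rm
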