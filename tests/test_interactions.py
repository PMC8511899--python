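"""Contact detection, subsite assignment and the interaction table."""

import numpy as np
import pytest

from tunnelflex.interactions import (
    assign_subsites,
    find_hbonds,
    find_salt_bridges,
    interaction_table,
)
from tunnelflex.structure import Structure
from tunnelflex.synthetic import (
    make_bfactor_fixture,
    make_complex_fixture,
    make_contact_fixture,
    make_glycan_chain,
    make_ring_fixture,
)


class TestContactDetection:
    def test_hydroxyl_pair_within_cutoff_found(self):
        st = make_contact_fixture([("SER", "OG", "O3", 2.9)])
        records = find_hbonds(st)
        assert len(records) == 1
        rec = records[0]
        assert (rec.donor_residue[0], rec.donor_atom) == ("S", "OG")
        assert rec.acceptor_atom == "O3"
        assert rec.distance == pytest.approx(2.9, abs=0.01)

    def test_pair_beyond_cutoff_ignored(self):
        st = make_contact_fixture([("TYR", "OH", "O3", 3.7)])
        assert find_hbonds(st, cutoff=3.6) == []

    def test_salt_bridge_arg_to_carboxylate(self):
        st = make_contact_fixture([("ARG", "NH1", "O6B", 2.9)])
        records = find_salt_bridges(st)
        assert len(records) == 1
        assert records[0].kind == "SALT BRIDGE"
        assert records[0].distance == pytest.approx(2.9, abs=0.01)

    def test_lys_nz_to_carboxylate(self):
        st = make_contact_fixture([("LYS", "NZ", "O6A", 3.0)])
        assert len(find_salt_bridges(st)) == 1

    def test_salt_bridge_pairs_excluded_from_hbonds(self):
        st = make_contact_fixture([("ARG", "NH1", "O6B", 2.9)])
        sb = {(r.donor_atom, r.acceptor_atom) for r in find_salt_bridges(st)}
        hb = {(r.donor_atom, r.acceptor_atom) for r in find_hbonds(st)}
        assert sb and not (sb & hb)

    def test_histidine_contact_is_hbond_not_salt_bridge(self):
        st = make_contact_fixture([("HIS", "NE2", "O2", 2.9)])
        assert len(find_hbonds(st)) == 1
        assert find_salt_bridges(st) == []

    def test_batch_distances_recovered_to_hundredth_angstrom(self, rng):
        donors = [("SER", "OG", "O3"), ("TYR", "OH", "O2"), ("ASN", "ND2", "O1"),
                  ("GLN", "NE2", "O4"), ("ARG", "NH1", "O6B"), ("LYS", "NZ", "O6A"),
                  ("THR", "OG1", "O3"), ("TRP", "NE1", "O2"), ("HIS", "ND1", "O4"),
                  ("ARG", "NE", "O6B")]
        for resname, datom, satom in donors:
            d = float(rng.uniform(2.5, 3.5))
            st = make_contact_fixture([(resname, datom, satom, d)])
            records = find_hbonds(st, cutoff=3.6) + find_salt_bridges(st)
            match = [r for r in records
                     if r.donor_atom == datom and r.acceptor_atom == satom]
            assert len(match) == 1
            assert match[0].distance == pytest.approx(d, abs=0.01)

    def test_cutoff_monotonicity(self):
        st = make_contact_fixture(
            [("SER", "OG", "O3", 2.9), ("TYR", "OH", "O2", 3.4)]
        )
        def key(r):
            return (r.donor_residue, r.donor_atom, r.acceptor_atom)
        for lo, hi in [(2.5, 3.0), (3.0, 3.5), (3.5, 4.0)]:
            small = {key(r) for r in find_hbonds(st, cutoff=lo)}
            large = {key(r) for r in find_hbonds(st, cutoff=hi)}
            assert small <= large

    def test_nonpositive_cutoff_rejected(self):
        st = make_contact_fixture([("SER", "OG", "O3", 2.9)])
        with pytest.raises(ValueError, match="> 0"):
            find_hbonds(st, cutoff=0.0)
        with pytest.raises(ValueError, match="> 0"):
            find_salt_bridges(st, cutoff=-1.0)

    def test_rigid_body_invariance(self, rng, complex_structure):
        base, _ = interaction_table(
            complex_structure, __import__("tunnelflex").default_region_map()
        )
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = complex_structure.transformed(q, np.array([11.0, -4.0, 7.0]))
        rotated, _ = interaction_table(
            moved, __import__("tunnelflex").default_region_map()
        )
        assert len(base) == len(rotated)
        for a, b in zip(base, rotated):
            assert (a.donor_residue, a.donor_atom, a.acceptor_atom) == (
                b.donor_residue, b.donor_atom, b.acceptor_atom
            )
            assert a.distance == pytest.approx(b.distance, abs=1e-6)


class TestSubsites:
    def test_three_sugar_chain_numbered_plus1_minus1_minus2(self, complex_structure):
        assn = assign_subsites(complex_structure)
        by_seq = {seq: sub for (_, seq), sub in assn.subsites.items()}
        assert by_seq == {601: +1, 701: -1, 801: -2}

    def test_scissile_bond_flanked_by_catalytic_pair(self, complex_structure):
        assn = assign_subsites(complex_structure)
        (chain, seq, atom), (minus1, plus1) = assn.scissile_bond
        assert (seq, atom) == (601, "O4")
        assert (minus1, plus1) == ("BEM701", "BEM601")

    def test_single_sugar_gets_plus_one(self):
        ring = make_ring_fixture("4C1")
        triad = make_bfactor_fixture(
            b_profile=15.0, residue_ids=["N167", "H168", "Y222"]
        )
        st = Structure(chains={**triad.chains, **ring.chains})
        assn = assign_subsites(st)
        assert list(assn.subsites.values()) == [+1]
        assert assn.scissile_bond is None

    def test_four_sugar_chain_extends_numbering(self):
        st = make_complex_fixture(n_sugars=4)
        assn = assign_subsites(st)
        assert sorted(assn.subsites.values()) == [-3, -2, -1, 1]

    def test_disconnected_ligand_rejected(self):
        sugars = make_glycan_chain(2)
        # teleport the second sugar far away: no glycosidic link remains
        for atom in sugars[1].atoms:
            atom.coord = atom.coord + np.array([50.0, 0.0, 0.0])
        triad = make_bfactor_fixture(
            b_profile=15.0, residue_ids=["N167", "H168", "Y222"]
        )
        st = Structure(chains={**triad.chains, "B": sugars})
        with pytest.raises(ValueError, match="disconnected|connected"):
            assign_subsites(st)

    def test_no_ligand_yields_empty_assignment(self, uniform_structure):
        assn = assign_subsites(uniform_structure)
        assert assn.subsites == {}


class TestInteractionTable:
    def test_apo_structure_yields_empty_table(self, uniform_structure):
        records, counts = interaction_table(
            uniform_structure, __import__("tunnelflex").default_region_map()
        )
        assert records == []
        assert counts == {"H-BOND": 0, "SALT BRIDGE": 0}

    def test_requested_contacts_present_with_regions(self, complex_structure,
                                                     region_map):
        records, counts = interaction_table(complex_structure, region_map)
        by_key = {(r.donor_residue, r.donor_atom, r.acceptor_residue): r
                  for r in records}
        sb = by_key[("R215", "NH1", "BEM601")]
        assert sb.kind == "SALT BRIDGE"
        assert sb.distance == pytest.approx(2.9, abs=0.01)
        assert sb.subsite == +1
        assert sb.region == "EXIT SITE (exit_ring_i)"
        hb = by_key[("Y38", "OH", "BEM701")]
        assert hb.kind == "H-BOND"
        assert hb.subsite == -1
        assert hb.region == "TUNNEL SITE (iLW)"
        assert counts["SALT BRIDGE"] == 1

    def test_records_ordered_entry_tunnel_exit(self, complex_structure, region_map):
        records, _ = interaction_table(complex_structure, region_map)
        site_rank = {"TUNNEL": 1, "EXIT": 2, "ENTRY": 0}
        ranks = [site_rank[r.region.split()[0]] for r in records if r.region]
        assert ranks == sorted(ranks)

    def test_counts_ignore_distal_subsites(self, region_map):
        # one contact at +1 and one at -2: only the former is counted
        st = make_complex_fixture(
            contacts=[
                ("ARG", 215, "NH1", 0, "O6B", 2.9),
                ("ASN", 55, "ND2", 2, "O3", 3.0),
            ]
        )
        records, counts = interaction_table(st, region_map)
        subsites = {r.donor_residue: r.subsite for r in records}
        assert subsites["N55"] == -2
        assert counts == {"H-BOND": 0, "SALT BRIDGE": 1}

    def test_contact_to_glycosidic_oxygen_marked_bridging(self, region_map):
        st = make_complex_fixture(
            contacts=[("TYR", 38, "OH", 0, "O4", 2.6)]
        )
        records, counts = interaction_table(st, region_map)
        bridging = [r for r in records if r.donor_residue == "Y38"
                    and r.acceptor_residue == "BEM601" and r.acceptor_atom == "O4"]
        assert len(bridging) == 1
        assert bridging[0].distance == pytest.approx(2.6, abs=0.01)
        assert bridging[0].subsite == (-1, +1)
        assert bridging[0].subsite_label() == "[-1, +1]"
        assert counts["H-BOND"] >= 1
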