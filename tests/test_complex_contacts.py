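from __future__ import annotations

import numpy as np
import pytest

from aptascreen.complex_contacts import (
    AtomRecord,
    contact_report,
    find_hbonds,
    find_hydrophobic,
    parse_structure,
)
from aptascreen.synthetic_data import gen_complex_pdb


def _atom(name, resname, xyz, chain="A", resnum=1, element=None):
    if element is None:
        element = name[0]
    return AtomRecord(chain, resname, resnum, name, element, *xyz)


def _pdb_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" "):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {name[0]:>2s}\n"
    )


class TestParse:
    def test_two_residue_toy(self):
        text = _pdb_line(1, "CA", "GLY", "A", 1, 1.0, 2.0, 3.0) + _pdb_line(
            2, "P", "A", "B", 1, 4.0, 5.0, 6.0
        )
        atoms = parse_structure(text)
        assert len(atoms) == 2
        assert atoms[0].residue_name == "GLY" and atoms[0].xyz.tolist() == [1.0, 2.0, 3.0]
        assert atoms[1].chain == "B" and atoms[1].xyz.tolist() == [4.0, 5.0, 6.0]

    def test_waters_excluded_by_default(self):
        text = "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
        assert parse_structure(text) == []
        assert len(parse_structure(text, keep_waters=True)) == 1

    def test_altloc_resolved_to_highest_occupancy(self):
        text = _pdb_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, occ=0.4, altloc="A")
        text += _pdb_line(2, "CA", "GLY", "A", 1, 9.0, 9.0, 9.0, occ=0.6, altloc="B")
        atoms = parse_structure(text)
        assert len(atoms) == 1
        assert atoms[0].x == 9.0
        # occupancy tie goes to conformer A
        text = _pdb_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, occ=0.5, altloc="A")
        text += _pdb_line(2, "CA", "GLY", "A", 1, 9.0, 9.0, 9.0, occ=0.5, altloc="B")
        assert parse_structure(text)[0].x == 0.0

    def test_malformed_coordinates_rejected_with_line_number(self):
        good = _pdb_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0)
        bad = good.replace("   0.000", "  xx.000", 1)
        with pytest.raises(ValueError, match="line 2"):
            parse_structure(good + bad)


class TestHBonds:
    def test_donor_acceptor_inside_window(self):
        prot = [_atom("NZ", "LYS", (0, 0, 0))]
        rna = [_atom("OP1", "A", (3.0, 0, 0), chain="B")]
        bonds = find_hbonds(prot, rna)
        assert len(bonds) == 1
        assert bonds[0].donor.atom_name == "NZ"
        assert bonds[0].distance == pytest.approx(3.0)

    def test_pair_beyond_default_cutoff(self):
        prot = [_atom("NZ", "LYS", (0, 0, 0))]
        rna = [_atom("OP1", "A", (4.0, 0, 0), chain="B")]
        assert find_hbonds(prot, rna) == []

    def test_pair_below_minimum_distance(self):
        prot = [_atom("NZ", "LYS", (0, 0, 0))]
        rna = [_atom("OP1", "A", (1.5, 0, 0), chain="B")]
        assert find_hbonds(prot, rna) == []

    def test_rna_donor_to_protein_acceptor_direction(self):
        prot = [_atom("OD1", "ASP", (0, 0, 0))]
        rna = [_atom("N6", "A", (2.9, 0, 0), chain="B")]
        bonds = find_hbonds(prot, rna)
        assert len(bonds) == 1
        assert bonds[0].donor.atom_name == "N6"

    def test_untypable_atoms_never_bond(self):
        prot = [_atom("CB", "ALA", (0, 0, 0))]
        rna = [_atom("OP1", "A", (3.0, 0, 0), chain="B")]
        assert find_hbonds(prot, rna) == []


class TestHydrophobic:
    def test_apolar_pair_inside_cutoff(self):
        prot = [_atom("CB", "ALA", (0, 0, 0))]
        rna = [_atom("C5'", "A", (3.5, 0, 0), chain="B")]
        contacts = find_hydrophobic(prot, rna)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.5)

    def test_carbonyl_carbon_excluded_by_typing(self):
        # GLN CD is the amide carbonyl carbon: polar, never hydrophobic
        prot = [_atom("CD", "GLN", (0, 0, 0))]
        rna = [_atom("C5'", "A", (3.0, 0, 0), chain="B")]
        assert find_hydrophobic(prot, rna) == []

    def test_counts_monotone_in_cutoff(self):
        prot = [_atom("CB", "ALA", (0, 0, 0)), _atom("CB", "ALA", (0, 4.5, 0), resnum=2)]
        rna = [_atom("C5'", "A", (3.5, 0, 0), chain="B")]
        n_tight = len(find_hydrophobic(prot, rna, d_max=3.6))
        n_loose = len(find_hydrophobic(prot, rna, d_max=6.0))
        assert n_tight <= n_loose
        assert (n_tight, n_loose) == (1, 2)


class TestPlantedComplexes:
    @pytest.mark.parametrize("k_hb, k_ph, seed", [(3, 2, 0), (0, 0, 1), (5, 7, 11), (1, 0, 2)])
    def test_detection_recovers_planted_counts(self, k_hb, k_ph, seed):
        atoms = parse_structure(gen_complex_pdb(k_hb, k_ph, seed=seed))
        prot = [a for a in atoms if a.is_protein]
        rna = [a for a in atoms if a.is_nucleic]
        report = contact_report(prot, rna)
        assert (report.n_hbonds, report.n_hydrophobic) == (k_hb, k_ph)

    def test_argument_order_changes_labels_not_counts(self):
        atoms = parse_structure(gen_complex_pdb(4, 3, seed=5))
        prot = [a for a in atoms if a.is_protein]
        rna = [a for a in atoms if a.is_nucleic]
        fwd = contact_report(prot, rna)
        rev = contact_report(rna, prot)
        assert (fwd.n_hbonds, fwd.n_hydrophobic) == (rev.n_hbonds, rev.n_hydrophobic)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        atoms = parse_structure(gen_complex_pdb(3, 4, seed=9))
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = np.array([7.0, -3.0, 11.0])

        def moved(a):
            x, y, z = rot @ a.xyz + shift
            return AtomRecord(a.chain, a.residue_name, a.residue_number,
                              a.atom_name, a.element, x, y, z)

        moved_atoms = [moved(a) for a in atoms]
        before = contact_report([a for a in atoms if a.is_protein],
                                [a for a in atoms if a.is_nucleic])
        after = contact_report([a for a in moved_atoms if a.is_protein],
                               [a for a in moved_atoms if a.is_nucleic])
        assert (before.n_hbonds, before.n_hydrophobic) == (after.n_hbonds, after.n_hydrophobic)
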