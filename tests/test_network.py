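"""Hydrogen bonds, hydrophobic tethers and constraint-network assembly."""

import numpy as np
import pytest

from riborigid.model import read_structure
from riborigid.network import (Bar, ConstraintNetwork, add_ligand_constraints,
                               build_network, detect_hbonds,
                               detect_hydrophobics, hbond_energy)
from riborigid.synthetic import make_binding_triplet

from conftest import MG_WATER_PDB


def _nh_o_fixture(d_no: float, angle_dha: float) -> str:
    """Two-residue fixture with one N-H donor aimed at a carbonyl O.

    The hydrogen sits on the N-O axis rotated to produce the requested
    D-H...A angle.
    """
    import math
    # exact construction: H at the origin, donor along +x at 1.0 A, and
    # the acceptor placed so that angle(D, H, A) is exactly angle_dha
    # while |D - A| equals d_no
    h = np.zeros(3)
    n = np.array([1.0, 0.0, 0.0])
    ct = math.cos(math.radians(angle_dha))
    r = ct + math.sqrt(max(ct * ct - 1.0 + d_no * d_no, 0.0))
    o = r * np.array([math.cos(math.radians(angle_dha)),
                      math.sin(math.radians(angle_dha)), 0.0])
    rows = [
        ("N3", "N", 15, "U", n), ("H3", "H", 15, "U", h),
        ("C2", "C", 15, "U", n + np.array([-1.3, 0.5, 0.0])),
        ("C4", "C", 15, "U", n + np.array([-1.3, -0.9, 0.0])),
        ("O4", "O", 16, "U", o),
        ("C4", "C", 16, "U", o + np.array([1.2, 0.0, 0.0])),
    ]
    lines = []
    for k, (name, el, resseq, base, xyz) in enumerate(rows, start=1):
        lines.append(f"ATOM  {k:5d}  {name:<3s} {base:>3s} A{resseq:4d}"
                     f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                     f"  1.00  0.00          {el:>2s}")
    return "\n".join(lines) + "\nEND\n"


class TestDetectHbonds:
    @pytest.mark.parametrize("d_no,angle,found", [
        (2.9, 180.0, True),    # ideal geometry
        (3.6, 180.0, False),   # beyond the 3.5 A cutoff
        (2.9, 110.0, False),   # below the 120 deg cutoff
        (3.45, 125.0, True),   # just inside both cutoffs
    ])
    def test_geometric_criteria(self, d_no, angle, found):
        st = read_structure(_nh_o_fixture(d_no, angle))
        hbs = detect_hbonds(st, place_hydrogens=False)
        assert (len(hbs) == 1) == found
        if found:
            assert hbs[0].distance_DA == pytest.approx(d_no, abs=1e-3)

    def test_sorted_and_deterministic(self, quadruple_wt):
        a = detect_hbonds(quadruple_wt, place_hydrogens=False)
        b = detect_hbonds(quadruple_wt, place_hydrogens=False)
        assert [(h.donor, h.acceptor) for h in a] == \
            [(h.donor, h.acceptor) for h in b]
        assert [(h.donor, h.acceptor) for h in a] == \
            sorted((h.donor, h.acceptor) for h in a)


class TestHbondEnergy:
    def test_ideal_geometry_is_the_global_minimum(self):
        e0 = hbond_energy(2.8, 180.0)
        assert e0 == pytest.approx(-8.0)
        for d in (2.5, 3.0, 3.3):
            for ang in (130.0, 150.0, 170.0):
                assert hbond_energy(d, ang) >= e0

    def test_weaker_with_distance_beyond_optimum(self):
        assert hbond_energy(2.9, 170.0) <= hbond_energy(3.4, 170.0)

    def test_weaker_with_bending(self):
        assert hbond_energy(2.9, 175.0) <= hbond_energy(2.9, 130.0)

    def test_salt_bridge_always_below_cutoffs(self):
        e = hbond_energy(3.4, 125.0, salt_bridge=True)
        assert e < -1.0 < -0.6


class TestHydrophobics:
    def _pair(self, gap):
        d = 2 * 1.70 + gap
        rows = [("C5", "C", 15, d)]
        lines = [
            f"ATOM      1  C5    U A  15       0.000   0.000   0.000"
            f"  1.00  0.00           C",
            f"ATOM      2  C5    U A  16    {d:8.3f}   0.000   0.000"
            f"  1.00  0.00           C",
        ]
        return read_structure("\n".join(lines) + "\nEND\n")

    def test_contact_within_threshold(self):
        st = self._pair(0.1)
        assert detect_hydrophobics(st) == [(0, 1)]

    def test_separated_pair_has_no_tether(self):
        st = self._pair(5.0)
        assert detect_hydrophobics(st) == []

    def test_matches_brute_force_on_the_quadruple(self, quadruple_wt):
        st = quadruple_wt
        found = set(detect_hydrophobics(st))
        neigh = {}
        for i, j in st.bonds:
            neigh.setdefault(i, set()).add(j)
            neigh.setdefault(j, set()).add(i)
        expected = set()
        for i in range(st.n_atoms):
            for j in range(i + 1, st.n_atoms):
                if st.atoms[i].element not in "CS" or \
                        st.atoms[j].element not in "CS":
                    continue
                if j in neigh.get(i, ()) or \
                        neigh.get(i, set()) & neigh.get(j, set()):
                    continue
                d = np.linalg.norm(st.coords[i] - st.coords[j])
                if d - 3.4 <= 0.25:
                    expected.add((i, j))
        assert found == expected


class TestBuildNetwork:
    def test_e_cut_filters_weak_bonds(self, quadruple_wt):
        hbs = detect_hbonds(quadruple_wt, place_hydrogens=False)
        weak = [h for h in hbs if h.energy > -0.6]
        net = build_network(quadruple_wt, e_cut=-0.6, hbonds=hbs)
        kept = {(b.i, b.j) for b in net.bars if b.provenance == "HBOND"}
        for h in weak:
            pair = (min(net.body_of_atom[h.donor],
                        net.body_of_atom[h.acceptor]),
                    max(net.body_of_atom[h.donor],
                        net.body_of_atom[h.acceptor]))
            assert pair not in kept

    def test_lower_cutoff_is_a_subset(self, quadruple_wt):
        n06 = build_network(quadruple_wt, e_cut=-0.6)
        n10 = build_network(quadruple_wt, e_cut=-1.0)
        hb06 = {b.key() for b in n06.bars if b.provenance == "HBOND"}
        hb10 = {b.key() for b in n10.bars if b.provenance == "HBOND"}
        assert hb10 <= hb06

    def test_positive_cutoff_rejected(self, quadruple_wt):
        with pytest.raises(ValueError, match="negative|attractive"):
            build_network(quadruple_wt, e_cut=0.1)

    def test_hexahydrated_mg_bars(self):
        st = read_structure(MG_WATER_PDB)
        net = build_network(st, e_cut=-0.6)
        mg_bars = [b for b in net.bars if b.provenance == "MG_COORD"]
        assert len(mg_bars) == 6

    def test_bulk_water_outside_shell_dropped(self):
        text = MG_WATER_PDB.replace("END", (
            "HETATM    8  O   HOH A 207      20.0  20.0  20.0  1.00  0.00"
            "           O\nEND"))
        st = read_structure(text)
        net = build_network(st, e_cut=-0.6)
        assert net.n_bodies == 7   # Mg + 6 shell waters, bulk water gone

    def test_deterministic_serialisation(self, quadruple_wt):
        t1 = build_network(quadruple_wt, e_cut=-0.6).to_text()
        t2 = build_network(quadruple_wt, e_cut=-0.6).to_text()
        assert t1 == t2

    def test_network_text_round_trip(self, quadruple_wt):
        net = build_network(quadruple_wt, e_cut=-0.6)
        net2 = ConstraintNetwork.from_text(net.to_text())
        assert net2.bar_key_set() == net.bar_key_set()
        assert net2.n_bodies == net.n_bodies
        assert net2.e_cut == net.e_cut


class TestLigandConstraints:
    def test_additive_and_idempotent(self):
        st = make_binding_triplet()
        net = build_network(st, e_cut=-0.6)
        lig = add_ligand_constraints(net)
        assert net.bar_key_set() <= lig.bar_key_set()
        lig2 = add_ligand_constraints(lig)
        assert lig2.bar_key_set() == lig.bar_key_set()
        new = [b for b in lig.bars if b.provenance == "LIGAND"]
        assert len(new) == 3   # pairwise over the three nucleobases

    def test_input_network_not_modified(self):
        st = make_binding_triplet()
        net = build_network(st, e_cut=-0.6)
        before = net.bar_key_set()
        add_ligand_constraints(net)
        assert net.bar_key_set() == before

    def test_missing_binding_nucleotide_rejected(self, quadruple_wt):
        net = build_network(quadruple_wt, e_cut=-0.6)
        with pytest.raises(ValueError, match="47"):
            add_ligand_constraints(net)
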