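"""Hydrogen-bond energetics/detection, tethers, and network assembly."""

import numpy as np
import pytest

from abflex.network import (
    MissingHydrogensError,
    build_constraint_network,
    covalent_bonds,
    detect_hbonds,
    detect_tethers,
    hbond_energy,
    BARS,
    R0,
    V0,
)
from abflex.structure import AntibodyStructure, AtomRecord
from abflex.synth import ToyLoopSpec, make_toy_loop


def _atom(name, elem, chain, num, xyz, res="ALA", icode=""):
    return AtomRecord(name, elem, chain, num, icode, res, np.array(xyz, float), 10.0)


class TestHbondEnergy:
    def _ideal(self, r_da):
        donor = np.array([0.0, 0.0, 0.0])
        hydrogen = np.array([1.01, 0.0, 0.0])
        acceptor = np.array([r_da, 0.0, 0.0])
        # base at 120 deg from the H-A axis
        base = acceptor + 1.23 * np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 0])
        return donor, hydrogen, acceptor, base

    def test_minimum_at_equilibrium_distance(self):
        d, h, a, b = self._ideal(R0)
        assert hbond_energy(d, h, a, b) == pytest.approx(-V0, abs=1e-9)

    def test_vanishes_at_long_range(self):
        d, h, a, b = self._ideal(10 * R0)
        assert abs(hbond_energy(d, h, a, b)) < 1e-8

    def test_radial_polynomial_at_3p2(self):
        # independent evaluation of 8*(5 (2.8/3.2)^12 - 6 (2.8/3.2)^10)
        ratio = 2.8 / 3.2
        expected = 8.0 * (5 * ratio**12 - 6 * ratio**10)
        d, h, a, b = self._ideal(3.2)
        assert hbond_energy(d, h, a, b) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-4.570938135846514, abs=1e-9)

    def test_continuity_and_minimum_location(self):
        # attractive branch only (the radial term crosses zero at
        # R0*sqrt(5/6) ~ 2.56 A and rises steeply below)
        rs = np.linspace(2.6, 12.0, 2000)
        es = []
        for r in rs:
            d, h, a, b = self._ideal(r)
            es.append(hbond_energy(d, h, a, b))
        es = np.array(es)
        assert np.all(np.abs(np.diff(es)) < 0.5)  # no jumps on a fine grid
        assert abs(rs[np.argmin(es)] - R0) < 0.05

    def test_angular_factor_caps_magnitude(self):
        d, h, a, b = self._ideal(R0)
        bent_h = np.array([0.6, 0.82, 0.0])  # off-axis hydrogen
        assert abs(hbond_energy(d, bent_h, a, b)) < V0

    def test_degenerate_geometry_rejected(self):
        z = np.zeros(3)
        with pytest.raises(ValueError, match="degenerate"):
            hbond_energy(z, z, np.array([1.0, 0, 0]))


class TestDetectHbonds:
    def test_engineered_bond_recovered_with_planned_energy(self, loop_bonded):
        s, truth = loop_bonded
        bonds = detect_hbonds(s)
        assert len(bonds) == 1
        assert bonds[0].energy == pytest.approx(-4.0, abs=0.1)

    def test_sorted_strongest_first(self, loop_two_energy):
        s, _ = loop_two_energy
        energies = [b.energy for b in detect_hbonds(s)]
        assert energies == sorted(energies)
        assert energies[0] == pytest.approx(-5.5, abs=0.1)

    def test_extended_chain_has_no_bonds(self, loop_plain):
        s, _ = loop_plain
        assert detect_hbonds(s) == []

    def test_far_pair_not_bonded(self):
        atoms = [
            _atom("N", "N", "H", 95, [0, 0, 0]),
            _atom("H", "H", "H", 95, [1.0, 0, 0]),
            _atom("CA", "C", "H", 95, [-0.8, 1.2, 0]),
            _atom("O", "O", "H", 97, [5.0, 0, 0]),
            _atom("C", "C", "H", 97, [5.8, 1.0, 0]),
            _atom("CA", "C", "H", 97, [7.2, 1.2, 0]),
        ]
        s = AntibodyStructure(atoms=atoms)
        assert detect_hbonds(s) == []

    def test_missing_hydrogens_raise_unless_fallback(self, loop_plain):
        s, _ = loop_plain
        stripped = AntibodyStructure([a for a in s.atoms if a.element != "H"], s.model_id)
        with pytest.raises(MissingHydrogensError, match="protonate"):
            detect_hbonds(stripped)
        # fallback path places amide hydrogens and runs the screens
        assert isinstance(detect_hbonds(stripped, place_missing_hydrogens=True), list)


class TestDetectTethers:
    @staticmethod
    def _pair(distance):
        # two separated methyl-like carbons on non-adjacent residues
        atoms = [
            _atom("CA", "C", "H", 95, [0, 0, 0], res="GLY"),
            _atom("CB", "C", "H", 95, [0, 1.5, 0]),
            _atom("CA", "C", "H", 99, [50, 0, 0], res="GLY"),
            _atom("CB", "C", "H", 99, [0, 1.5 + distance, 0]),
        ]
        return AntibodyStructure(atoms=atoms)

    def test_within_vdw_plus_slop(self):
        tethers = detect_tethers(self._pair(3.5))
        assert len(tethers) == 1
        assert tethers[0].bars == 2

    def test_beyond_threshold_no_tether(self):
        assert detect_tethers(self._pair(4.0)) == []

    def test_matches_brute_force_scan(self, loop_two_energy):
        """Tether list equals an all-pairs distance scan with the same rules."""
        s, _ = loop_two_energy
        bonds = covalent_bonds(s)
        adj = {i: set() for i in range(len(s.atoms))}
        for i, j, _ in bonds:
            adj[i].add(j)
            adj[j].add(i)

        def graphdist_gt3(i, j):
            seen = {i}
            frontier = {i}
            for _ in range(3):
                frontier = {y for x in frontier for y in adj[x]} - seen
                seen |= frontier
            return j not in seen

        vdw = {"C": 1.7, "S": 1.8}
        expected = set()
        for i, ai in enumerate(s.atoms):
            for j in range(i + 1, len(s.atoms)):
                aj = s.atoms[j]
                if ai.element not in vdw or aj.element not in vdw:
                    continue
                if ai.residue_key == aj.residue_key:
                    continue
                cut = vdw[ai.element] + vdw[aj.element] + 0.25
                if np.linalg.norm(ai.position - aj.position) <= cut and graphdist_gt3(i, j):
                    expected.add((i, j))
        got = {(t.i, t.j) for t in detect_tethers(s)}
        assert got == expected


class TestBuildNetwork:
    def test_cutoff_keeps_bonds_at_or_below(self, loop_two_energy):
        s, _ = loop_two_energy
        hb = detect_hbonds(s)

        def hbond_edges(cutoff):
            nw = build_constraint_network(s, cutoff, hbonds=hb)
            return [e for e in nw.edges if e.kind == "hbond"]

        assert {round(e.energy, 1) for e in hbond_edges(-3.0)} == {-5.5}
        assert len(hbond_edges(0.0)) == len(hb)  # all retained at zero
        assert hbond_edges(-6.9) == []

    def test_edge_count_monotone_in_cutoff(self, loop_two_energy):
        s, _ = loop_two_energy
        hb = detect_hbonds(s)
        te = detect_tethers(s)
        counts = [
            len(build_constraint_network(s, c, hbonds=hb, tethers=te).edges)
            for c in (0.0, -1.0, -3.0, -5.0, -7.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_positive_cutoff_rejected(self, loop_plain):
        s, _ = loop_plain
        with pytest.raises(ValueError, match="cutoff"):
            build_constraint_network(s, 0.5)

    def test_unknown_residue_named_in_error(self):
        s = AntibodyStructure(atoms=[_atom("CA", "C", "H", 95, [0, 0, 0], res="XYZ")])
        with pytest.raises(ValueError, match="XYZ"):
            build_constraint_network(s, 0.0, hbonds=[], tethers=[])

    def test_bar_table(self, loop_bonded):
        s, _ = loop_bonded
        nw = build_constraint_network(s, 0.0)
        by_kind = {e.kind: e.bars for e in nw.edges}
        assert by_kind["covalent_rotatable"] == 5
        assert by_kind["covalent_locked"] == 6
        assert by_kind["hbond"] == 5
        assert BARS["tether"] == 2
        assert all(e.energy is not None for e in nw.edges if e.kind == "hbond")

    def test_covalent_subnetwork_connected(self, loop_plain):
        s, _ = loop_plain
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(s.atoms)))
        g.add_edges_from((i, j) for i, j, _ in covalent_bonds(s))
        assert nx.is_connected(g)
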