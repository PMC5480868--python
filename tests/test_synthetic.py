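"""Generators: determinism and their documented statistical contracts."""

import numpy as np
import pytest

from riborigid.network import add_ligand_constraints
from riborigid.rigidity import pebble_game_decompose
from riborigid.stats import HBondSpec, hbond_occupancy
from riborigid.synthetic import (CoopDesign, IonSpec, QUADRUPLE_BONDS_MUT,
                                 QUADRUPLE_BONDS_WT, TelegraphBond,
                                 TrajectorySpec, design_nucleotide_ids,
                                 estimate_coop, filter_hbond_bars,
                                 make_binding_triplet, make_fixture_network,
                                 simulate_condition_ensembles,
                                 simulate_trajectory, toy_snapshot_network)
from riborigid import detect_hbonds, build_network


class TestFixtureNetworks:
    def test_braced_pair_shape(self):
        net = make_fixture_network("braced_pair")
        assert net.n_bodies == 2
        assert net.total_bar_count() == 6

    def test_chain_modes(self):
        res = pebble_game_decompose(make_fixture_network("chain", n=4))
        assert res.floppy_modes_internal == 3

    def test_random_is_seed_deterministic(self):
        a = make_fixture_network("random", n=8, seed=1)
        b = make_fixture_network("random", n=8, seed=1)
        assert a.bar_key_set() == b.bar_key_set()

    def test_random_size_capped(self):
        with pytest.raises(ValueError):
            make_fixture_network("random", n=60, seed=0)


class TestQuadruple:
    def test_wildtype_has_the_seven_designed_bonds(self, quadruple_wt):
        hbs = detect_hbonds(quadruple_wt, place_hydrogens=False)
        got = {(quadruple_wt.atoms[h.donor].nucleotide_id,
                quadruple_wt.atoms[h.donor].name,
                quadruple_wt.atoms[h.acceptor].nucleotide_id,
                quadruple_wt.atoms[h.acceptor].name) for h in hbs}
        expected = {(dn, da, an, aa)
                    for dn, da, _h, an, aa in QUADRUPLE_BONDS_WT}
        assert got == expected
        assert len(hbs) == 7

    def test_mutant_loses_exactly_two_bonds(self, quadruple_mut):
        hbs = detect_hbonds(quadruple_mut, place_hydrogens=False)
        got = {(quadruple_mut.atoms[h.donor].nucleotide_id,
                quadruple_mut.atoms[h.donor].name,
                quadruple_mut.atoms[h.acceptor].nucleotide_id,
                quadruple_mut.atoms[h.acceptor].name) for h in hbs}
        expected = {(dn, da, an, aa)
                    for dn, da, _h, an, aa in QUADRUPLE_BONDS_MUT}
        assert got == expected
        assert len(hbs) == 5

    def test_mutant_drops_the_34_37_pairing(self, quadruple_mut):
        hbs = detect_hbonds(quadruple_mut, place_hydrogens=False)
        pairs = {frozenset((quadruple_mut.atoms[h.donor].nucleotide_id,
                            quadruple_mut.atoms[h.acceptor].nucleotide_id))
                 for h in hbs}
        assert frozenset((34, 37)) not in pairs
        assert frozenset((34, 65)) in pairs


class TestToyAptamer:
    def test_binding_triplet_separate_until_ligand_added(self, toy):
        st, _ = toy
        rng = np.random.default_rng(2)
        net = toy_snapshot_network(st, "apt", rng)
        apo = pebble_game_decompose(filter_hbond_bars(net, -0.6))
        clusters = {apo.cluster_ids[net.body_for(n, "N1")]
                    for n in (47, 51, 74)}
        # empty binding site: the three nucleobases never form one
        # rigid cluster (they may pairwise co-rigidify through the
        # surrounding helices in some snapshots)
        assert len(clusters) >= 2
        lig = pebble_game_decompose(
            filter_hbond_bars(add_ligand_constraints(net), -0.6))
        lig_clusters = {lig.cluster_ids[lig.network.body_for(n, "N1")]
                        for n in (47, 51, 74)}
        assert len(lig_clusters) == 1

    def test_full_atom_triplet_mirrors_the_contract(self):
        st = make_binding_triplet()
        net = build_network(st, e_cut=-0.6)
        apo = pebble_game_decompose(net)
        assert len({apo.cluster_ids[net.body_for(n, "N1")]
                    for n in (47, 51, 74)}) == 3
        lig = pebble_game_decompose(add_ligand_constraints(net))
        assert len({lig.cluster_ids[net.body_for(n, "N1")]
                    for n in (47, 51, 74)}) == 1

    def test_snapshots_are_seed_deterministic(self, toy):
        st, _ = toy
        a = toy_snapshot_network(st, "apt", np.random.default_rng(5))
        b = toy_snapshot_network(st, "apt", np.random.default_rng(5))
        assert a.bar_key_set() == b.bar_key_set()

    def test_filter_monotone_in_e_cut(self, toy):
        st, _ = toy
        net = toy_snapshot_network(st, "loop", np.random.default_rng(8))
        strict = filter_hbond_bars(net, -1.0).bar_key_set()
        loose = filter_hbond_bars(net, -0.6).bar_key_set()
        assert strict <= loose


class TestConditionEnsembles:
    def test_membership_frequency_matches_q(self):
        design = CoopDesign(n_snapshots=1000, n_trajectories=1, seed=4)
        nets = simulate_condition_ensembles(design)
        for condition in nets:
            q = design.q_of(condition)
            attached = np.mean([
                any(b.provenance == "HBOND" for b in net.bars)
                for net in nets[condition][0]])
            assert abs(attached - q) < 3 * np.sqrt(q * (1 - q) / 1000)

    def test_same_seed_reproduces_the_estimate(self):
        r1, _ = estimate_coop(CoopDesign(seed=9, n_snapshots=200))
        r2, _ = estimate_coop(CoopDesign(seed=9, n_snapshots=200))
        assert r1.value(15) == r2.value(15)

    def test_null_design_is_centred(self):
        res, _ = estimate_coop(
            CoopDesign(0.6, 0.6, 0.6, 0.6, n_snapshots=1000, seed=21))
        assert abs(res.value(15)) < 3 * res.sem[0]


class TestSimulateTrajectory:
    def test_zero_sigma_means_zero_rmsf(self, toy):
        st, regions = toy
        from riborigid.trajectory import rmsf
        ens = simulate_trajectory(
            st, TrajectorySpec(sigma_default=0.0, global_motion=True,
                               n_frames=10), seed=0, regions=regions)
        prof = rmsf(ens)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-6)

    def test_region_sigma_ordering_recovered(self, toy):
        st, regions = toy
        from riborigid.trajectory import rmsf
        spec = TrajectorySpec(sigma_by_region={"P2": 0.1, "J2/3": 0.8},
                              sigma_default=0.3, n_frames=150)
        ens = simulate_trajectory(st, spec, seed=1, regions=regions)
        prof = rmsf(ens)
        p2 = np.mean([prof.value(i) for i in regions.members("P2")])
        j23 = np.mean([prof.value(i) for i in regions.members("J2/3")])
        assert p2 < j23

    def test_telegraph_occupancy_matches_stationary_fraction(self, toy):
        st, regions = toy
        bond = TelegraphBond((34, "N1"), (65, "N1"), on_fraction=0.7,
                             mean_dwell_frames=5.0)
        ens = simulate_trajectory(
            st, TrajectorySpec(hbonds=[bond], sigma_default=0.05,
                               n_frames=800), seed=6, regions=regions)
        table = hbond_occupancy(
            ens, [HBondSpec((34, "N1"), None, (65, "N1"))],
            block_length=1000.0)
        assert abs(table.occupancy[0] - 70.0) < 3 * max(table.sem[0], 1.0)

    def test_shedding_ion_loses_a_water(self, toy):
        st, regions = toy
        from riborigid.trajectory import mg_hydration
        ion = IonSpec((0.0, 0.0, 40.0), "shed", shed_frame=5)
        ens = simulate_trajectory(
            st, TrajectorySpec(ions=[ion], sigma_default=0.0,
                               global_motion=False, n_frames=10),
            seed=0, regions=regions)
        hyd = mg_hydration(ens)
        assert hyd.water_counts[0, 0] == 6
        assert hyd.water_counts[-1, 0] == 5
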