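"""p_lrc, delta p_lrc, Coop and occupancy statistics."""

import math

import numpy as np
import pytest

from riborigid.model import read_ensemble, read_structure
from riborigid.stats import (HBondSpec, OccupancyTable, PlrcProfile,
                             basepair_occupancy, coop, coop_ttest,
                             decompose_ensemble, delta_plrc,
                             hbond_occupancy, plrc_profile)
from riborigid.synthetic import (CoopDesign, design_nucleotide_ids,
                                 simulate_condition_ensembles)


def profile(values, ids=None, n=100, n_traj=3, rng=None):
    """PlrcProfile with given pooled probabilities and small trajectory
    scatter so SEMs are positive."""
    values = np.asarray(values, float)
    ids = list(ids or range(15, 15 + len(values)))
    rng = rng or np.random.default_rng(0)
    per = np.clip(values + rng.normal(0, 0.01, (n_traj, len(values))),
                  1e-6, 1.0)
    per = per - per.mean(axis=0) + values   # pooled mean stays exact
    return PlrcProfile(ids, values, np.round(values * n).astype(int), n,
                       per)


class TestPlrcProfile:
    def test_fraction_of_snapshots(self):
        design = CoopDesign(n_snapshots=4, n_trajectories=1, seed=3)
        nets = simulate_condition_ensembles(design)["apo_apt"][0]
        results = decompose_ensemble(nets)
        ids = design_nucleotide_ids(design)
        prof = plrc_profile(results, nucleotide_ids=ids)
        attached = sum(
            1 for net in nets
            if any(b.provenance == "HBOND" for b in net.bars))
        assert prof.value(15) == pytest.approx(attached / 4)

    def test_fully_rigid_network_gives_ones(self):
        from riborigid.network import Bar, ConstraintNetwork
        labels = [(15, "N1"), (16, "N1"), (17, "N1")]
        net = ConstraintNetwork(3, [Bar(0, 1, 6, "COVALENT_LOCKED"),
                                    Bar(1, 2, 6, "COVALENT_LOCKED")],
                                body_labels=labels)
        results = decompose_ensemble([net] * 5)
        prof = plrc_profile(results, nucleotide_ids=[15, 16, 17])
        assert np.allclose(prof.p, 1.0)

    def test_bernoulli_design_recovers_q(self):
        design = CoopDesign(n_snapshots=1000, n_trajectories=1, seed=11)
        nets = simulate_condition_ensembles(design)["apo_apt"][0]
        prof = plrc_profile(decompose_ensemble(nets),
                            nucleotide_ids=design_nucleotide_ids(design))
        q = design.q_apo_apt
        bound = 3 * math.sqrt(q * (1 - q) / 1000)
        assert abs(prof.value(15) - q) < bound


class TestDeltaPlrc:
    def test_identical_profiles_give_zero(self):
        p = profile([0.4, 0.8])
        d = delta_plrc(p, p)
        assert np.allclose(d.delta, 0.0)

    def test_bound_attained(self):
        lig = profile([1.0])
        apo = profile([1e-9])
        d = delta_plrc(lig, apo)
        assert d.delta[0] == pytest.approx(1.0, abs=1e-6)

    def test_mean_and_sem_match_hand_computation(self):
        ids = [15]
        lig = PlrcProfile(ids, np.array([0.6]), np.array([60]), 100,
                          np.array([[0.5], [0.6], [0.7]]))
        apo = PlrcProfile(ids, np.array([0.3]), np.array([30]), 100,
                          np.array([[0.2], [0.3], [0.4]]))
        d = delta_plrc(lig, apo)
        diffs = np.array([0.3, 0.3, 0.3])
        assert d.delta[0] == pytest.approx(0.3)
        assert d.sem[0] == pytest.approx(diffs.std(ddof=1) / math.sqrt(3))

    def test_mismatched_nucleotides_rejected(self):
        with pytest.raises(ValueError):
            delta_plrc(profile([0.5], ids=[15]), profile([0.5], ids=[16]))


class TestCoop:
    def test_identical_profiles_give_zero(self):
        p = profile([0.5] * 3, ids=[15, 16, 17])
        res = coop(p, p, p, p, nucleotides={15, 16, 17})
        assert np.allclose(res.coop, 0.0, atol=1e-12)

    def test_purely_additive_effects_cancel(self):
        la = profile([0.8], ids=[15])
        aa = profile([0.4], ids=[15])
        ll = profile([0.4], ids=[15])
        al = profile([0.2], ids=[15])
        res = coop(la, aa, ll, al, nucleotides={15})
        assert res.coop[0] == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        la = profile([0.9], ids=[15])
        aa = profile([0.6], ids=[15])
        ll = profile([0.7], ids=[15])
        al = profile([0.5], ids=[15])
        res = coop(la, aa, ll, al, nucleotides={15})
        assert res.coop[0] == pytest.approx(math.log(0.45 / 0.42),
                                            abs=1e-12)

    def test_identity_between_the_two_forms(self, rng):
        ps = rng.uniform(0.05, 0.95, (4, 5))
        profs = [profile(p, ids=[15, 16, 17, 18, 19]) for p in ps]
        res = coop(*profs, nucleotides={15, 16, 17, 18, 19})
        direct = (np.log(ps[0]) + np.log(ps[3])
                  - np.log(ps[1]) - np.log(ps[2]))
        assert np.allclose(res.coop, direct, atol=1e-12)

    def test_sem_by_error_propagation(self):
        profs = [profile([q], ids=[15]) for q in (0.9, 0.6, 0.7, 0.5)]
        res = coop(*profs, nucleotides={15})
        expected = math.sqrt(sum(
            (p.sem()[0] / p.p[0]) ** 2 for p in profs))
        assert res.sem[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_probability_flagged_not_dropped(self):
        la = profile([0.9], ids=[15])
        aa = PlrcProfile([15], np.array([0.0]), np.array([0]), 100,
                         np.zeros((3, 1)))
        ll = profile([0.7], ids=[15])
        al = profile([0.5], ids=[15])
        res = coop(la, aa, ll, al, nucleotides={15})
        assert np.isnan(res.coop[0])
        assert 15 in res.undefined_reason

    def test_continuity_correction_yields_finite_value(self):
        la = profile([0.9], ids=[15])
        aa = PlrcProfile([15], np.array([0.0]), np.array([0]), 100,
                         np.full((3, 1), 1e-4))
        ll = profile([0.7], ids=[15])
        al = profile([0.5], ids=[15])
        res = coop(la, aa, ll, al, nucleotides={15},
                   continuity_correction=True)
        assert np.isfinite(res.coop[0])


class TestCoopTtest:
    def test_zero_coop_is_not_significant(self):
        res = coop_ttest(_coop_result([0.0], [0.1]), df=2)
        assert res.p_value[0] == pytest.approx(1.0)
        assert res.stars[0] == "ns"

    def test_huge_t_is_three_stars(self):
        res = coop_ttest(_coop_result([5.0], [1e-6]), df=2)
        assert res.p_value[0] < 1e-3
        assert res.stars[0] == "***"

    def test_documented_df2_worked_check(self):
        # reconstruction with df = 2 (three trajectories)
        res = coop_ttest(_coop_result([0.065], [0.021]), df=2)
        assert res.t[0] == pytest.approx(3.095, abs=0.01)
        assert res.p_value[0] == pytest.approx(0.0904, abs=0.002)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            coop_ttest(_coop_result([0.1], [0.1]), df=0)


def _coop_result(vals, sems):
    from riborigid.stats import CoopResult
    return CoopResult([15] * len(vals), np.array(vals, float),
                      np.array(sems, float))


class TestOccupancy:
    def _ensemble(self, distances, spacing=20.0):
        st = read_structure(
            "ATOM      1  N3    U A  15       0.0   0.0   0.0  1.00  0.00"
            "           N\n"
            "ATOM      2  O4    U A  16       3.0   0.0   0.0  1.00  0.00"
            "           O\nEND\n")
        frames = []
        for d in distances:
            c = st.coords.copy()
            c[1, 0] = d
            frames.append(c)
        return read_ensemble(st, frames, frame_spacing=spacing)

    def test_always_bonded_is_hundred_percent(self):
        ens = self._ensemble([3.0] * 50)
        t = hbond_occupancy(ens, [HBondSpec((15, "N3"), None, (16, "O4"))],
                            block_length=200.0)
        assert t.occupancy[0] == pytest.approx(100.0)
        assert t.sem[0] == pytest.approx(0.0)

    def test_alternating_frames_give_half(self):
        ens = self._ensemble([3.0, 5.0] * 50)
        t = hbond_occupancy(ens, [HBondSpec((15, "N3"), None, (16, "O4"))],
                            block_length=200.0)
        assert t.occupancy[0] == pytest.approx(50.0)
        assert t.sem[0] == pytest.approx(0.0, abs=1e-9)

    def test_block_length_must_fit(self):
        ens = self._ensemble([3.0] * 10)
        with pytest.raises(ValueError, match="block"):
            hbond_occupancy(ens, [HBondSpec((15, "N3"), None, (16, "O4"))],
                            block_length=10000.0)

    def test_mean_invariant_to_block_length(self):
        ens = self._ensemble([3.0, 3.0, 5.0] * 40)
        spec = [HBondSpec((15, "N3"), None, (16, "O4"))]
        t1 = hbond_occupancy(ens, spec, block_length=200.0)
        t2 = hbond_occupancy(ens, spec, block_length=600.0)
        assert t1.occupancy[0] == pytest.approx(t2.occupancy[0])


class TestBasepairOccupancy:
    def _table(self, occs, sems):
        labels = [f"b{k}" for k in range(len(occs))]
        return OccupancyTable(labels, np.array(occs, float),
                              np.array(sems, float))

    def test_mean_over_members(self):
        t = basepair_occupancy(self._table([100.0, 50.0], [0, 0]),
                               {"pair": ["b0", "b1"]})
        assert t.occupancy[0] == pytest.approx(75.0)

    def test_single_member_unchanged(self):
        t = basepair_occupancy(self._table([62.0], [3.0]),
                               {"pair": ["b0"]})
        assert t.occupancy[0] == pytest.approx(62.0)
        assert t.sem[0] == pytest.approx(3.0)

    def test_sem_propagation(self):
        t = basepair_occupancy(self._table([50, 60, 70], [2, 2, 2]),
                               {"pair": ["b0", "b1", "b2"]})
        assert t.sem[0] == pytest.approx(2.0 / math.sqrt(3))

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            basepair_occupancy(self._table([50.0], [1.0]), {"pair": []})
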