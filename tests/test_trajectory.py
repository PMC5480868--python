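"""Trajectory metrics: fitting invariance and closed-form checks."""

import math

import numpy as np
import pytest
from scipy import stats as sstats

from riborigid.model import Ensemble, read_ensemble
from riborigid.trajectory import (chi_histogram, mg_hydration,
                                  occupancy_grid, pca_project, rac,
                                  radius_of_gyration, rmsd_series, rmsf,
                                  select_core)
from riborigid.synthetic import (IonSpec, TrajectorySpec, make_toy_aptamer,
                                 simulate_trajectory)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture(scope="module")
def toy_struct():
    return make_toy_aptamer()


class TestRmsf:
    def test_identical_frames_give_zero(self, toy_struct):
        st, _ = toy_struct
        ens = read_ensemble(st, [st.coords.copy() for _ in range(4)])
        prof = rmsf(ens)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_rigid_motion_removed_by_fitting(self, toy_struct, rng):
        st, _ = toy_struct
        frames = []
        for _ in range(5):
            R = random_rotation(rng)
            frames.append(st.coords @ R.T + rng.normal(size=3) * 10)
        prof = rmsf(read_ensemble(st, frames))
        assert np.allclose(prof.rmsf, 0.0, atol=1e-6)

    def test_isotropic_jitter_approaches_sigma_sqrt3(self, toy_struct,
                                                     rng):
        st, _ = toy_struct
        sigma = 0.3
        frames = [st.coords + rng.normal(0, sigma, st.coords.shape)
                  for _ in range(400)]
        prof = rmsf(read_ensemble(st, frames))
        assert prof.per_atom.mean() == pytest.approx(
            sigma * math.sqrt(3), rel=0.05)

    def test_empty_fit_selection_rejected(self, toy_struct):
        st, _ = toy_struct
        ens = read_ensemble(st, [st.coords.copy()] * 2)
        with pytest.raises(ValueError):
            rmsf(ens, fit_nucleotides=[9999])


class TestSelectCore:
    def test_aptamer_core_is_54_of_67(self, toy_struct, rng):
        st, _ = toy_struct
        frames = [st.coords + rng.normal(0, 0.2, st.coords.shape)
                  for _ in range(10)]
        prof = rmsf(read_ensemble(st, frames))
        assert len(select_core(prof, 0.8)) == 54

    def test_fraction_one_keeps_all(self, toy_struct, rng):
        st, _ = toy_struct
        frames = [st.coords + rng.normal(0, 0.2, st.coords.shape)
                  for _ in range(5)]
        prof = rmsf(read_ensemble(st, frames))
        assert len(select_core(prof, 1.0)) == 67

    def test_tie_broken_toward_lower_id(self):
        from riborigid.trajectory import RmsfProfile
        prof = RmsfProfile([15, 16, 17, 18], np.array([1.0, 2.0, 2.0, 3.0]),
                           np.zeros(4), [15, 16, 17, 18])
        sel = select_core(prof, 0.5)
        assert sel.nucleotide_ids == [15, 16]

    def test_invalid_fraction_rejected(self, toy_struct, rng):
        st, _ = toy_struct
        frames = [st.coords + rng.normal(0, 0.2, st.coords.shape)
                  for _ in range(3)]
        prof = rmsf(read_ensemble(st, frames))
        with pytest.raises(ValueError):
            select_core(prof, 0.0)


class TestRmsd:
    def test_reference_frame_gives_zero(self, toy_struct):
        st, _ = toy_struct
        ens = read_ensemble(st, [st.coords.copy()] * 3)
        series = rmsd_series(ens)
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_translation_removed(self, toy_struct):
        st, _ = toy_struct
        ens = read_ensemble(st, [st.coords + np.array([3.0, 0, 0])])
        series = rmsd_series(ens, reference=st.coords)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_substructure_displacement_measured(self, toy_struct):
        st, regions = toy_struct
        moved = st.coords.copy()
        import numpy as np
        p1 = {i for i, a in enumerate(st.atoms)
              if a.nucleotide_id in set(regions.members("P1"))}
        for i in p1:
            moved[i] += np.array([0.0, 0.0, 2.0])
        ens = read_ensemble(st, [moved])
        core = [i for i in st.nucleotide_ids()
                if i not in set(regions.members("P1"))]
        series = rmsd_series(ens, reference=st.coords,
                             fit_nucleotides=core,
                             measure_nucleotides=regions.members("P1"))
        assert series.values[0] == pytest.approx(2.0, abs=1e-9)


class TestRadiusOfGyration:
    def test_collinear_unit_masses(self):
        # three atoms at 0, 1, 2 A -> Rg = sqrt(2/3)
        text = "".join(
            f"ATOM  {k + 1:5d}  N{k + 1}    U A  1{5 + k}    "
            f"{float(k):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           N\n"
            for k in range(3)) + "END\n"
        from riborigid.model import read_structure
        st = read_structure(text)
        series = radius_of_gyration(st, exclude_region=None)
        assert series.values[0] == pytest.approx(math.sqrt(2.0 / 3.0),
                                                 abs=1e-9)

    def test_rotation_invariance(self, toy_struct, rng):
        st, regions = toy_struct
        base = radius_of_gyration(st, regions).values[0]
        rotated = st.with_coords(st.coords @ random_rotation(rng).T + 5.0)
        assert radius_of_gyration(rotated, regions).values[0] == \
            pytest.approx(base, abs=1e-9)

    def test_p1_excluded_by_default(self, toy_struct):
        st, regions = toy_struct
        with_p1 = radius_of_gyration(st, regions,
                                     exclude_region=None).values[0]
        without = radius_of_gyration(st, regions).values[0]
        assert without != pytest.approx(with_p1)

    def test_too_small_selection_rejected(self, toy_struct):
        st, regions = toy_struct
        table = {i: "P1" for i in st.nucleotide_ids()}
        from riborigid.model import assign_regions
        allp1 = assign_regions(st, table)
        with pytest.raises(ValueError):
            radius_of_gyration(st, allp1)


class TestRac:
    def test_constant_trajectory_is_zero(self, toy_struct):
        st, _ = toy_struct
        ens = read_ensemble(st, [st.coords.copy()] * 10)
        curve = rac(ens)
        assert np.allclose(curve.rac, 0.0, atol=1e-9)

    def test_rac1_equals_mean_rmsd(self, toy_struct, rng):
        st, _ = toy_struct
        frames = [st.coords + rng.normal(0, 0.3, st.coords.shape)
                  for _ in range(30)]
        ens = read_ensemble(st, frames)
        curve = rac(ens)
        series = rmsd_series(ens)
        assert curve.value(1) == pytest.approx(series.mean(), rel=1e-9)

    def test_white_noise_follows_inverse_sqrt_window(self, toy_struct,
                                                     rng):
        st, _ = toy_struct
        sigma = 0.3
        frames = [st.coords + rng.normal(0, sigma, st.coords.shape)
                  for _ in range(400)]
        ens = read_ensemble(st, frames)
        curve = rac(ens, reference=st.coords,
                    windows=[1, 4, 16, 64])
        scaled = curve.rac * np.sqrt(curve.window)
        assert np.allclose(scaled, scaled[0], rtol=0.06)


class TestPca:
    def test_single_mode_explains_everything(self, toy_struct, rng):
        st, _ = toy_struct
        direction = np.zeros(st.coords.shape)
        p_idx = [i for i, a in enumerate(st.atoms) if a.name == "P"]
        direction[p_idx[0]] = [1.0, 0, 0]
        frames = [st.coords + t * direction
                  for t in rng.normal(0, 1.0, 50)]
        proj = pca_project(read_ensemble(st, frames))
        assert proj.explained[0] == pytest.approx(1.0, abs=1e-6)

    def test_projections_are_centred(self, toy_struct, rng):
        st, _ = toy_struct
        frames = [st.coords + rng.normal(0, 0.3, st.coords.shape)
                  for _ in range(40)]
        proj = pca_project(read_ensemble(st, frames))
        pooled = np.concatenate(proj.projections)
        assert np.allclose(pooled.mean(axis=0), 0.0, atol=1e-9)

    def test_anisotropic_variance_ratio_recovered(self, toy_struct, rng):
        st, _ = toy_struct
        p_idx = [i for i, a in enumerate(st.atoms) if a.name == "P"]
        d1 = np.zeros(st.coords.shape)
        d2 = np.zeros(st.coords.shape)
        d1[p_idx[0]] = [1.0, 0, 0]
        d2[p_idx[1]] = [0, 1.0, 0]
        s1, s2 = 2.0, 1.0
        frames = [st.coords + rng.normal(0, s1) * d1
                  + rng.normal(0, s2) * d2 for _ in range(3000)]
        proj = pca_project(read_ensemble(st, frames))
        ratio = proj.eigenvalues[0] / proj.eigenvalues[1]
        assert ratio == pytest.approx((s1 / s2) ** 2, rel=0.15)


class TestHydration:
    def _ens(self, shift=None, chelate=False):
        st, regions = make_toy_aptamer()
        ion = IonSpec(tuple(st.coords.mean(axis=0) + [0, 0, 30.0]),
                      "fixed")
        ens = simulate_trajectory(
            st, TrajectorySpec(sigma_default=0.0, global_motion=False,
                               ions=[ion], n_frames=3), seed=0,
            regions=regions)
        frames = ens.frames.copy()
        top = ens.topology
        widx = [i for i, a in enumerate(top.atoms)
                if a.category == "WATER"]
        if shift is not None:
            frames[:, widx[0], :] += shift
        if chelate:
            mg = [i for i, a in enumerate(top.atoms)
                  if a.category == "MG"][0]
            rna0 = [i for i, a in enumerate(top.atoms)
                    if a.category == "RNA"][0]
            frames[:, mg, :] = frames[:, rna0, :] + [2.2, 0, 0]
        return Ensemble(top, frames)

    def test_six_close_waters_is_hexahydrated(self):
        hyd = mg_hydration(self._ens())
        assert hyd.water_counts[0, 0] == 6
        assert hyd.is_hexahydrated(0, 0)

    def test_one_water_outside_cutoff_breaks_hexahydration(self):
        hyd = mg_hydration(self._ens(shift=np.array([1.6, 0, 0])))
        assert hyd.water_counts[0, 0] == 5
        assert not hyd.is_hexahydrated(0, 0)

    def test_close_rna_atom_sets_chelation(self):
        hyd = mg_hydration(self._ens(chelate=True))
        assert hyd.chelated[0, 0]
        assert not hyd.is_hexahydrated(0, 0)


class TestOccupancyGrid:
    def test_fixed_ion_site_fully_occupied(self, toy_struct):
        st, regions = toy_struct
        site = tuple(st.coords.mean(axis=0) + [0, 0, 25.0])
        ens = simulate_trajectory(
            st, TrajectorySpec(sigma_default=0.05,
                               ions=[IonSpec(site, "fixed")],
                               n_frames=20), seed=1, regions=regions)
        grid = occupancy_grid(ens, sites={"s": np.array(site)})
        assert grid.site_occupancy["s"] == pytest.approx(100.0)
        assert grid.counts.max() <= ens.n_frames

    def test_invalid_spacing_rejected(self, toy_struct):
        st, _ = toy_struct
        ens = read_ensemble(st, [st.coords.copy()] * 2)
        with pytest.raises(ValueError):
            occupancy_grid(ens, spacing=0.0)

    def test_uniform_ion_counts_pass_chi_square(self, toy_struct, rng):
        st, _ = toy_struct
        # a lone diffusing particle sampled uniformly in a box
        from riborigid.model import Atom, Structure
        import riborigid.chem as chem
        atoms = list(st.atoms) + [Atom(9000, "MG", "MG", None,
                                       chem.ATOMIC_MASS["MG"], "MG", "MG",
                                       ("M", 999, "MG"))]
        coords = np.vstack([st.coords, [[0.0, 0.0, 0.0]]])
        top = Structure(atoms, coords, st.nucleotides, st.bonds)
        frames = np.repeat(coords[None], 2000, axis=0)
        frames[:, -1, :] = rng.uniform(0, 8.0, (2000, 3)) + 100.0
        grid = occupancy_grid(Ensemble(top, frames), spacing=4.0,
                              align=False)
        occupied = grid.counts.flatten()
        occupied = occupied[occupied > 0]
        assert len(occupied) == 8          # the 2x2x2 cells of the box
        expected = 2000 / 8
        chi2 = (((occupied - expected) ** 2) / expected).sum()
        p = sstats.chi2.sf(chi2, len(occupied) - 1)
        assert p > 0.01


class TestChiHistogram:
    def test_identical_frames_fill_one_bin(self, quadruple_wt):
        ens = read_ensemble(quadruple_wt,
                            [quadruple_wt.coords.copy()] * 3)
        hist = chi_histogram(ens)
        # base-only nucleotides have no O4', so all are skipped
        assert hist.per_nucleotide == {} or all(
            (h > 0).sum() == 1 for h in hist.per_nucleotide.values())

    def test_hand_computed_dihedral_lands_in_its_bin(self):
        from riborigid.model import read_structure
        # O4'-C1'-N9-C4 arranged for a 90-degree torsion
        lines = [
            ("O4'", "O", (0.0, 1.0, -1.0)),
            ("C1'", "C", (0.0, 0.0, 0.0)),
            ("N9", "N", (1.5, 0.0, 0.0)),
            ("C4", "C", (1.5, 0.0, 1.0)),
            ("C8", "C", (2.2, -0.9, -0.4)),
        ]
        text = "".join(
            f"ATOM  {k + 1:5d} {name:>4s}   G A  15    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
            for k, (name, el, (x, y, z)) in enumerate(lines)) + "END\n"
        st = read_structure(text)
        ens = read_ensemble(st, [st.coords.copy()] * 2)
        hist = chi_histogram(ens, bin_width=5.0)
        assert 15 in hist.per_nucleotide
        h = hist.per_nucleotide[15]
        occupied = np.nonzero(h)[0]
        assert len(occupied) == 1
        lo = hist.bin_edges[occupied[0]]
        from riborigid.geom import dihedral
        expected = dihedral(*(st.coords[k] for k in range(4)))
        assert lo <= expected < lo + 5.0

    def test_histograms_are_normalised(self, quadruple_wt, rng):
        frames = [quadruple_wt.coords
                  + rng.normal(0, 0.05, quadruple_wt.coords.shape)
                  for _ in range(5)]
        ens = read_ensemble(quadruple_wt, frames)
        hist = chi_histogram(ens)
        for h in hist.per_nucleotide.values():
            assert h.sum() == pytest.approx(1.0)
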