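"""Trajectory-level analyses for aptamer ensembles.

RMSF with core-nucleotide fitting, RMSD against a reference (whole RNA or
substructure), radius of gyration omitting a region, RMSD-average
correlation (RAC), PCA of phosphorus coordinates, Mg2+ hydration and
chelation tracking, ion occupancy grids and chi-dihedral histograms.

All superpositions are mass-weighted least-squares fits over the selected
atoms; every metric is invariant to global rotation/translation of the
input frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import chem
from .geom import dihedral, kabsch, rmsd
from .model import Ensemble, RegionMap, Structure


def _atom_indices(topology: Structure, nucleotides, heavy_only=False):
    sel = set(nucleotides)
    idx = [i for i, a in enumerate(topology.atoms)
           if a.category == "RNA" and a.nucleotide_id in sel
           and not (heavy_only and a.element == "H")]
    if not idx:
        raise ValueError("empty atom selection")
    return np.array(idx)


def _fit_frames(frames, reference, fit_idx, masses):
    """Fit every frame onto the reference over ``fit_idx`` atoms."""
    w = masses[fit_idx]
    out = np.empty_like(frames)
    for k, f in enumerate(frames):
        R, t = kabsch(f[fit_idx], reference[fit_idx], w)
        out[k] = f @ R.T + t
    return out


# ---------------------------------------------------------------------------
# RMSF and core selection
# ---------------------------------------------------------------------------

@dataclass
class RmsfProfile:
    nucleotide_ids: list[int]
    rmsf: np.ndarray                  # per nucleotide, atom-averaged (A)
    per_atom: np.ndarray
    fit_nucleotides: list[int]
    per_trajectory: np.ndarray | None = None  # (n_traj, n_nuc)

    def sem(self) -> np.ndarray:
        t = self.per_trajectory
        if t is None or t.shape[0] < 2:
            return np.zeros(len(self.nucleotide_ids))
        return t.std(axis=0, ddof=1) / math.sqrt(t.shape[0])

    def value(self, nucleotide_id: int) -> float:
        return float(self.rmsf[self.nucleotide_ids.index(nucleotide_id)])


def rmsf(ensemble_or_list, fit_nucleotides=None,
         heavy_only: bool = False) -> RmsfProfile:
    """Atomic root-mean-square fluctuations, averaged per nucleotide.

    Frames are least-squares fitted on the atoms of ``fit_nucleotides``
    (default: all nucleotides) before fluctuations about the mean structure
    are computed. Pass a list of ensembles to get per-trajectory values
    with a cross-trajectory mean.
    """
    ensembles = ([ensemble_or_list] if isinstance(ensemble_or_list, Ensemble)
                 else list(ensemble_or_list))
    top = ensembles[0].topology
    ids = top.nucleotide_ids()
    if fit_nucleotides is None:
        fit_nucleotides = ids
    fit_idx = _atom_indices(top, fit_nucleotides, heavy_only)
    masses = top.masses()

    per_traj = []
    per_atom_all = []
    for ens in ensembles:
        if ens.n_frames < 2:
            raise ValueError("RMSF needs at least two frames")
        fitted = _fit_frames(ens.frames, ens.frames[0], fit_idx, masses)
        mean = fitted.mean(axis=0)
        per_atom = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
        per_atom_all.append(per_atom)
        per_nuc = []
        for nid in ids:
            sel = _atom_indices(top, [nid], heavy_only)
            per_nuc.append(per_atom[sel].mean())
        per_traj.append(per_nuc)
    per_traj = np.array(per_traj)
    return RmsfProfile(ids, per_traj.mean(axis=0),
                       np.mean(per_atom_all, axis=0),
                       sorted(fit_nucleotides), per_traj)


@dataclass
class CoreSelection:
    nucleotide_ids: list[int]     # the least-fluctuating fraction, sorted
    fraction: float

    def __len__(self):
        return len(self.nucleotide_ids)


def select_core(profile: RmsfProfile, fraction: float = 0.8) -> CoreSelection:
    """The ``round(fraction * n)`` least-fluctuating nucleotides.

    Ties at the cut are broken toward the lower nucleotide id. For the
    67-nucleotide aptamer at the default fraction this selects 54
    nucleotides.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = int(round(fraction * len(profile.nucleotide_ids)))
    order = sorted(range(len(profile.nucleotide_ids)),
                   key=lambda k: (profile.rmsf[k],
                                  profile.nucleotide_ids[k]))
    chosen = sorted(profile.nucleotide_ids[k] for k in order[:n])
    return CoreSelection(chosen, fraction)


# ---------------------------------------------------------------------------
# RMSD / Rg / RAC
# ---------------------------------------------------------------------------

@dataclass
class MetricSeries:
    values: np.ndarray
    times: np.ndarray | None = None
    label: str = ""

    def mean(self) -> float:
        return float(self.values.mean())


def rmsd_series(ensemble: Ensemble, reference: np.ndarray | None = None,
                fit_nucleotides=None, measure_nucleotides=None,
                heavy_only: bool = False) -> MetricSeries:
    """Per-frame RMSD of ``measure_nucleotides`` after a mass-weighted best
    fit over ``fit_nucleotides`` onto the reference (default: first frame).
    """
    top = ensemble.topology
    ids = top.nucleotide_ids()
    fit_idx = _atom_indices(top, fit_nucleotides or ids, heavy_only)
    meas_idx = _atom_indices(top, measure_nucleotides or ids, heavy_only)
    ref = ensemble.frames[0] if reference is None else np.asarray(reference)
    if ref.shape != (top.n_atoms, 3):
        raise ValueError("reference does not match topology")
    masses = top.masses()
    fitted = _fit_frames(ensemble.frames, ref, fit_idx, masses)
    vals = np.array([rmsd(f[meas_idx], ref[meas_idx], masses[meas_idx])
                     for f in fitted])
    return MetricSeries(vals, ensemble.times, "rmsd")


def radius_of_gyration(ensemble_or_structure,
                       regions: RegionMap | None = None,
                       exclude_region: str | None = "P1") -> MetricSeries:
    """Mass-weighted radius of gyration per frame, excluding one region.

    Works on an Ensemble or a single Structure (crystal-structure use).
    The default excludes the P1 helix, the convention for measuring the
    compactness of the junction-plus-loops body of the aptamer.
    """
    if isinstance(ensemble_or_structure, Structure):
        top = ensemble_or_structure
        frames = top.coords[None, :, :]
        times = None
    else:
        top = ensemble_or_structure.topology
        frames = ensemble_or_structure.frames
        times = ensemble_or_structure.times
    excluded: set[int] = set()
    if exclude_region is not None:
        if regions is None:
            raise ValueError("need a RegionMap to exclude a region")
        excluded = set(regions.members(exclude_region))
    idx = np.array([i for i, a in enumerate(top.atoms)
                    if a.category == "RNA"
                    and a.nucleotide_id not in excluded])
    if len(idx) < 2:
        raise ValueError("selection leaves fewer than two atoms")
    m = top.masses()[idx]
    vals = []
    for f in frames:
        x = f[idx]
        com = (m[:, None] * x).sum(axis=0) / m.sum()
        vals.append(math.sqrt(float(
            (m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum())))
    return MetricSeries(np.array(vals), times, "rg")


@dataclass
class RacCurve:
    window: np.ndarray
    rac: np.ndarray

    def value(self, w: int) -> float:
        return float(self.rac[list(self.window).index(w)])


def rac(ensemble: Ensemble, reference: np.ndarray | None = None,
        windows=None, fit_nucleotides=None,
        against_average: bool = False) -> RacCurve:
    """RMSD average correlation: structural-change time scales.

    For window length w, coordinates are running-averaged over w frames,
    each averaged structure is best-fitted to the reference (the first
    post-discard frame by default, or the trajectory average with
    ``against_average``), and RAC(w) is the mean RMSD. RAC(1) equals the
    plain mean RMSD to the reference.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RAC needs at least two frames")
    top = ensemble.topology
    ids = top.nucleotide_ids()
    fit_idx = _atom_indices(top, fit_nucleotides or ids)
    masses = top.masses()
    # remove global motion first: running averages are only meaningful
    # over aligned coordinates
    pre_ref = (ensemble.frames.mean(axis=0) if against_average and
               reference is None else
               ensemble.frames[0] if reference is None else
               np.asarray(reference))
    aligned = _fit_frames(ensemble.frames, pre_ref, fit_idx, masses)
    reference = pre_ref
    if windows is None:
        windows = [w for w in (1, 2, 5, 10, 20, 50, 100)
                   if w <= ensemble.n_frames]
    out_w, out_r = [], []
    for w in windows:
        if w > ensemble.n_frames:
            warnings.warn(f"window {w} exceeds frame count; truncated",
                          stacklevel=2)
            continue
        csum = np.cumsum(aligned, axis=0)
        avg = (csum[w - 1:] - np.concatenate(
            [np.zeros((1,) + csum.shape[1:]), csum[:-w]])) / w
        vals = []
        for f in avg:
            R, t = kabsch(f[fit_idx], reference[fit_idx], masses[fit_idx])
            vals.append(rmsd((f @ R.T + t)[fit_idx], reference[fit_idx],
                             masses[fit_idx]))
        out_w.append(w)
        out_r.append(float(np.mean(vals)))
    return RacCurve(np.array(out_w), np.array(out_r))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaProjection:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray               # (n_modes, 3*n_sel)
    projections: list[np.ndarray]          # per trajectory, (n_frames, 3)
    explained: np.ndarray


def pca_project(ensembles, atom_name: str = "P",
                n_components: int = 3) -> PcaProjection:
    """PCA of selected-atom coordinates pooled over trajectories.

    Frames are first fitted (mass-weighted, all selected atoms) to the
    first frame of the first trajectory; the covariance is pooled, and each
    trajectory's frames are projected onto the leading components.
    """
    ensembles = ([ensembles] if isinstance(ensembles, Ensemble)
                 else list(ensembles))
    top = ensembles[0].topology
    sel = np.array([i for i, a in enumerate(top.atoms)
                    if a.name == atom_name and a.category == "RNA"])
    if len(sel) == 0:
        raise ValueError(f"no atoms named {atom_name!r}")
    masses = top.masses()
    ref = ensembles[0].frames[0]
    blocks = []
    for ens in ensembles:
        fitted = _fit_frames(ens.frames, ref, sel, masses)
        blocks.append(fitted[:, sel, :].reshape(ens.n_frames, -1))
    pooled = np.concatenate(blocks, axis=0)
    mean = pooled.mean(axis=0)
    centred = pooled - mean
    cov = centred.T @ centred / max(len(pooled) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    n_avail = int((evals > 1e-12 * max(evals[0], 1e-300)).sum())
    k = min(n_components, max(n_avail, 1))
    proj = [(b - mean) @ evecs[:, :k] for b in blocks]
    total = evals.sum() if evals.sum() > 0 else 1.0
    return PcaProjection(evals[:k], evecs[:, :k].T, proj, evals[:k] / total)


# ---------------------------------------------------------------------------
# Mg2+ hydration / occupancy grid
# ---------------------------------------------------------------------------

@dataclass
class HydrationSeries:
    ion_atoms: list[int]
    water_counts: np.ndarray     # (n_frames, n_ions)
    chelated: np.ndarray         # bool, (n_frames, n_ions)
    hexahydrated_per_frame: np.ndarray

    def is_hexahydrated(self, frame: int, ion: int) -> bool:
        return bool(self.water_counts[frame, ion] == 6
                    and not self.chelated[frame, ion])


def mg_hydration(ensemble: Ensemble, cutoff: float = 3.5) -> HydrationSeries:
    """First-shell water counts and RNA chelation flags per Mg2+ ion.

    A water belongs to the first shell when its oxygen is within the cutoff
    of the ion; any RNA atom within the same cutoff marks the shell as
    incomplete (direct chelation). An ion is hexahydrated when it holds six
    shell waters and no chelation.
    """
    top = ensemble.topology
    ions = [i for i, a in enumerate(top.atoms) if a.category == "MG"]
    if not ions:
        warnings.warn("no Mg2+ ions in topology", stacklevel=2)
        return HydrationSeries([], np.zeros((ensemble.n_frames, 0), int),
                               np.zeros((ensemble.n_frames, 0), bool),
                               np.zeros(ensemble.n_frames, int))
    waters = np.array([i for i, a in enumerate(top.atoms)
                       if a.category == "WATER" and a.element == "O"])
    rna = np.array([i for i, a in enumerate(top.atoms)
                    if a.category == "RNA" and a.element != "H"])
    counts = np.zeros((ensemble.n_frames, len(ions)), int)
    chel = np.zeros((ensemble.n_frames, len(ions)), bool)
    for f, frame in enumerate(ensemble.frames):
        for k, ion in enumerate(ions):
            if len(waters):
                d = np.linalg.norm(frame[waters] - frame[ion], axis=1)
                counts[f, k] = int((d <= cutoff).sum())
            if len(rna):
                d = np.linalg.norm(frame[rna] - frame[ion], axis=1)
                chel[f, k] = bool((d < cutoff).any())
    hexa = ((counts == 6) & ~chel).sum(axis=1)
    return HydrationSeries(ions, counts, chel, hexa)


@dataclass
class GridMap:
    origin: np.ndarray
    spacing: float
    counts: np.ndarray               # (nx, ny, nz) frame counts
    site_occupancy: dict[str, float]  # percent of frames

    def to_text(self, target) -> None:
        with open(target, "w") as fh:
            fh.write(f"# origin {self.origin[0]:.3f} {self.origin[1]:.3f} "
                     f"{self.origin[2]:.3f}\n")
            fh.write(f"# spacing {self.spacing}\n")
            fh.write(f"# shape {self.counts.shape[0]} "
                     f"{self.counts.shape[1]} {self.counts.shape[2]}\n")
            nz = np.argwhere(self.counts > 0)
            for ix, iy, iz in nz:
                fh.write(f"{ix} {iy} {iz} {int(self.counts[ix, iy, iz])}\n")


def occupancy_grid(ensemble: Ensemble, spacing: float = 0.4,
                   sites: dict[str, np.ndarray] | None = None,
                   site_radius: float = 3.0, align: bool = True) -> GridMap:
    """Mg2+ occupancy grid plus named-site occupancies.

    Frames are first fitted onto the topology's reference coordinates
    over the RNA atoms (set ``align=False`` if they already share a frame
    of reference); cells count the frames in which any ion falls inside
    them; a named site is occupied in a frame when any ion is within
    ``site_radius`` of the site coordinate, expressed in the reference
    coordinate system.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    top = ensemble.topology
    frames = ensemble.frames
    if align:
        rna_idx = np.where(top.category_mask("RNA"))[0]
        if len(rna_idx):
            frames = _fit_frames(frames, top.coords, rna_idx, top.masses())
    ions = [i for i, a in enumerate(top.atoms) if a.category == "MG"]
    pts = frames[:, ions, :] if ions else \
        np.zeros((ensemble.n_frames, 0, 3))
    if ions:
        lo = pts.reshape(-1, 3).min(axis=0) - spacing
        hi = pts.reshape(-1, 3).max(axis=0) + spacing
    else:
        lo, hi = np.zeros(3), np.ones(3)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    counts = np.zeros(shape, int)
    for frame_pts in pts:
        cells = set()
        for p in frame_pts:
            c = tuple(((p - lo) // spacing).astype(int))
            cells.add(c)
        for c in cells:
            counts[c] += 1
    site_occ = {}
    for name, coord in (sites or {}).items():
        coord = np.asarray(coord, float)
        if ions:
            d = np.linalg.norm(pts - coord, axis=2)
            site_occ[name] = 100.0 * float((d <= site_radius).any(axis=1)
                                           .mean())
        else:
            site_occ[name] = 0.0
    return GridMap(lo, spacing, counts, site_occ)


# ---------------------------------------------------------------------------
# Chi dihedral histograms
# ---------------------------------------------------------------------------

@dataclass
class ChiHistogram:
    bin_edges: np.ndarray
    per_nucleotide: dict[int, np.ndarray]   # normalised
    pooled: np.ndarray


def chi_histogram(ensemble: Ensemble, bin_width: float = 5.0,
                  nucleotides=None) -> ChiHistogram:
    """Normalised histograms of the glycosidic chi dihedral over [0, 360).

    chi is O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for pyrimidines;
    nucleotides with missing atoms are skipped with a warning.
    """
    top = ensemble.topology
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    per: dict[int, np.ndarray] = {}
    pooled = np.zeros(len(edges) - 1)
    sel = nucleotides or top.nucleotide_ids()
    for nuc in top.nucleotides:
        if nuc.nucleotide_id not in sel:
            continue
        if nuc.base in chem.PURINES:
            quad = ("O4'", "C1'", "N9", "C4")
        else:
            quad = ("O4'", "C1'", "N1", "C2")
        try:
            idx = [top.atom_index(nuc.nucleotide_id, n) for n in quad]
        except KeyError:
            warnings.warn(f"nucleotide {nuc.nucleotide_id}: chi atoms "
                          "missing; skipped", stacklevel=2)
            continue
        angles = [dihedral(*(frame[i] for i in idx))
                  for frame in ensemble.frames]
        hist, _ = np.histogram(angles, bins=edges)
        per[nuc.nucleotide_id] = hist / hist.sum()
        pooled += hist
    if pooled.sum() > 0:
        pooled = pooled / pooled.sum()
    return ChiHistogram(edges, per, pooled)
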