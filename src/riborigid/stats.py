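"""Ensemble-level statistics: largest-rigid-cluster probabilities, their
ligand-induced differences, the cooperativity statistic Coop(i), and
hydrogen-bond / base-pair occupancies with block-averaged uncertainties.

For every snapshot of an ensemble a rigid-cluster decomposition says
whether the base N1 atom of nucleotide i sits in the largest rigid
cluster; across N snapshots

    p_lrc(i) = n1(i) / N .

The ligand effect is the profile difference

    dp_lrc(i) = p_lrc(i)_lig - p_lrc(i)_apo ,

and the cooperativity of tertiary (loop) interactions and ligand binding,
referenced to the mutant apo state which lacks both, is the log-odds-style
double difference

    Coop(i) = ln[ p_lig^apt * p_apo^loop / (p_apo^apt * p_lig^loop) ] .

Coop(i) > 0 means the two interactions together stabilise nucleotide i
more than the sum of their separate effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .model import Ensemble, Structure, TERMINAL_P1
from .network import ConstraintNetwork
from .rigidity import RigidityResult, pebble_game_decompose

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_class(p: float) -> str:
    for level, stars in SIGNIFICANCE_LEVELS:
        if p < level:
            return stars
    return "ns"


@dataclass
class PlrcProfile:
    """Per-nucleotide probability of largest-rigid-cluster membership."""

    nucleotide_ids: list[int]
    p: np.ndarray                       # pooled p_lrc per nucleotide
    counts: np.ndarray                  # pooled n1 per nucleotide
    n_snapshots: int
    per_trajectory: np.ndarray          # (n_traj, n_nuc) sub-profiles
    condition: str = ""

    def __post_init__(self):
        self.p = np.asarray(self.p, float)
        self.counts = np.asarray(self.counts)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p_lrc out of [0, 1]")

    @property
    def n_trajectories(self) -> int:
        return int(self.per_trajectory.shape[0])

    def sem(self) -> np.ndarray:
        """Standard error over per-trajectory p_lrc values."""
        t = self.per_trajectory
        if t.shape[0] < 2:
            return np.zeros(t.shape[1])
        return t.std(axis=0, ddof=1) / math.sqrt(t.shape[0])

    def value(self, nucleotide_id: int) -> float:
        return float(self.p[self.nucleotide_ids.index(nucleotide_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"nucleotide": self.nucleotide_ids,
                             "p_lrc": self.p, "n1": self.counts,
                             "sem": self.sem(),
                             "condition": self.condition})


@dataclass
class DeltaProfile:
    nucleotide_ids: list[int]
    delta: np.ndarray
    sem: np.ndarray

    def __post_init__(self):
        if np.any(np.abs(self.delta) > 1 + 1e-12):
            raise ValueError("delta p_lrc out of [-1, 1]")

    def value(self, nucleotide_id: int) -> float:
        return float(self.delta[self.nucleotide_ids.index(nucleotide_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"nucleotide": self.nucleotide_ids,
                             "delta_p_lrc": self.delta, "sem": self.sem})


@dataclass
class CoopResult:
    nucleotide_ids: list[int]
    coop: np.ndarray
    sem: np.ndarray
    t: np.ndarray | None = None
    p_value: np.ndarray | None = None
    stars: list[str] | None = None
    df: int | None = None
    undefined_reason: dict[int, str] = field(default_factory=dict)

    def value(self, nucleotide_id: int) -> float:
        return float(self.coop[self.nucleotide_ids.index(nucleotide_id)])

    def to_frame(self) -> pd.DataFrame:
        d = {"nucleotide": self.nucleotide_ids, "coop": self.coop,
             "sem": self.sem}
        if self.p_value is not None:
            d["t"] = self.t
            d["p"] = self.p_value
            d["class"] = self.stars
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# p_lrc
# ---------------------------------------------------------------------------

def _membership_matrix(results, net_or_topology, nucleotide_ids):
    """(n_snapshots, n_nuc) boolean: N1 body in largest cluster."""
    rows = []
    for res in results:
        net = res.network
        if net is None:
            raise ValueError("RigidityResult carries no network metadata")
        row = []
        for nid in nucleotide_ids:
            try:
                body = net.body_for(nid, "N1")
            except KeyError:
                raise ValueError(
                    f"N1 atom of nucleotide {nid} missing") from None
            row.append(res.in_largest(body))
        rows.append(row)
    return np.array(rows, dtype=bool)


def plrc_profile(results, topology: Structure | None = None,
                 nucleotide_ids: list[int] | None = None,
                 condition: str = "") -> PlrcProfile:
    """p_lrc over an ensemble of rigid-cluster decompositions.

    ``results`` is either a flat sequence of :class:`RigidityResult` (one
    pseudo-trajectory) or a sequence of such sequences (one per independent
    trajectory, kept separate for the SEM).
    """
    if not results:
        raise ValueError("no rigidity results")
    if isinstance(results[0], RigidityResult):
        trajectories = [list(results)]
    else:
        trajectories = [list(tr) for tr in results]
    if nucleotide_ids is None:
        if topology is None:
            raise ValueError("need a topology or explicit nucleotide ids")
        nucleotide_ids = topology.nucleotide_ids()

    per_traj = []
    total = np.zeros(len(nucleotide_ids))
    n_total = 0
    for tr in trajectories:
        m = _membership_matrix(tr, topology, nucleotide_ids)
        per_traj.append(m.mean(axis=0))
        total += m.sum(axis=0)
        n_total += m.shape[0]
    return PlrcProfile(list(nucleotide_ids), total / n_total,
                       total.astype(int), n_total,
                       np.array(per_traj), condition)


def decompose_ensemble(networks, cache: bool = True):
    """Pebble-game decompositions for many networks, memoised by bar set.

    Snapshots whose constraint networks are identical (a common situation
    for synthetic ensembles with a small number of stochastic bond states)
    are decomposed once. The decomposition is a pure function of the
    network, so the cache cannot change any result.
    """
    memo: dict[frozenset, RigidityResult] = {}
    out = []
    for net in networks:
        if not cache:
            out.append(pebble_game_decompose(net))
            continue
        key = net.bar_key_set()
        res = memo.get(key)
        if res is None:
            res = pebble_game_decompose(net)
            memo[key] = res
        out.append(res)
    return out


def delta_plrc(lig: PlrcProfile, apo: PlrcProfile) -> DeltaProfile:
    """Element-wise p_lrc difference (ligand minus apo) with SEM over the
    per-trajectory differences."""
    if lig.nucleotide_ids != apo.nucleotide_ids:
        raise ValueError("profiles cover different nucleotide sets")
    delta = lig.p - apo.p
    if (lig.per_trajectory.shape == apo.per_trajectory.shape
            and lig.per_trajectory.shape[0] > 1):
        d = lig.per_trajectory - apo.per_trajectory
        sem = d.std(axis=0, ddof=1) / math.sqrt(d.shape[0])
    else:
        sem = np.sqrt(lig.sem() ** 2 + apo.sem() ** 2)
    return DeltaProfile(list(lig.nucleotide_ids), delta, sem)


# ---------------------------------------------------------------------------
# Coop
# ---------------------------------------------------------------------------

def coop(lig_apt: PlrcProfile, apo_apt: PlrcProfile,
         lig_loop: PlrcProfile, apo_loop: PlrcProfile,
         nucleotides: set[int] | None = None,
         continuity_correction: bool = False) -> CoopResult:
    """Cooperativity of loop tertiary interactions and ligand binding.

    Coop(i) = ln(p_lig^apt / p_apo^loop)
              - [ln(p_apo^apt / p_apo^loop) + ln(p_lig^loop / p_apo^loop)]

    which reduces to ln[(p_lig^apt p_apo^loop) / (p_apo^apt p_lig^loop)].
    The SEM follows by error propagation from the four terms:
    SEM^2 = sum_k (SEM_pk / pk)^2. Nucleotides where any probability is
    zero are flagged undefined (NaN) rather than silently padded; the
    optional continuity correction replaces n1/N by (n1+1/2)/(N+1).
    """
    ids = sorted(nucleotides) if nucleotides is not None else \
        sorted(TERMINAL_P1 & set(lig_apt.nucleotide_ids))
    profiles = (lig_apt, apo_apt, lig_loop, apo_loop)
    for pr in profiles[1:]:
        if set(pr.nucleotide_ids) != set(profiles[0].nucleotide_ids):
            raise ValueError("the four profiles cover different nucleotides")

    vals = np.empty(len(ids))
    sems = np.empty(len(ids))
    undefined: dict[int, str] = {}
    for k, nid in enumerate(ids):
        ps, ss = [], []
        for pr in profiles:
            idx = pr.nucleotide_ids.index(nid)
            p = pr.p[idx]
            if continuity_correction:
                p = (pr.counts[idx] + 0.5) / (pr.n_snapshots + 1.0)
            ps.append(p)
            ss.append(pr.sem()[idx])
        if min(ps) <= 0.0:
            vals[k] = np.nan
            sems[k] = np.nan
            undefined[nid] = "zero probability in at least one condition"
            continue
        pla, paa, pll, pal = ps
        vals[k] = math.log(pla * pal / (paa * pll))
        sems[k] = math.sqrt(sum((s / p) ** 2 for p, s in zip(ps, ss)))
    return CoopResult(ids, vals, sems, undefined_reason=undefined)


def coop_ttest(res: CoopResult, df: int = 2) -> CoopResult:
    """Two-sided one-sample t-test of Coop(i) = 0.

    The default df of 2 corresponds to three independent trajectories per
    condition; the number of degrees of freedom is configurable because the
    exact choice for this design is a modelling decision.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.where(res.sem > 0, res.coop / res.sem, np.inf * np.sign(res.coop))
    t = np.where(res.coop == 0, 0.0, t)
    p = 2.0 * sstats.t.sf(np.abs(t), df)
    stars = [significance_class(pv) if np.isfinite(pv) else "ns"
             for pv in p]
    return CoopResult(res.nucleotide_ids, res.coop, res.sem,
                      t=t, p_value=p, stars=stars, df=df,
                      undefined_reason=dict(res.undefined_reason))


# ---------------------------------------------------------------------------
# Hydrogen-bond / base-pair occupancies
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    labels: list[str]
    occupancy: np.ndarray              # percent
    sem: np.ndarray                    # percent
    block_length: float | None = None
    per_trajectory: np.ndarray | None = None   # (n_traj, n_bonds) percent

    def __post_init__(self):
        if np.any((self.occupancy < 0) | (self.occupancy > 100 + 1e-9)):
            raise ValueError("occupancy out of [0, 100]")

    def value(self, label: str) -> float:
        return float(self.occupancy[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bond": self.labels,
                             "occupancy_pct": self.occupancy,
                             "sem_pct": self.sem})


@dataclass(frozen=True)
class HBondSpec:
    """Donor/acceptor atom specification for occupancy tracking."""
    donor: tuple[int, str]         # (nucleotide_id, atom name)
    hydrogen: tuple[int, str] | None
    acceptor: tuple[int, str]

    def label(self) -> str:
        return (f"{self.donor[0]}.{self.donor[1]}-"
                f"{self.acceptor[0]}.{self.acceptor[1]}")


def _bond_indicator(ens: Ensemble, spec: HBondSpec,
                    max_distance: float, min_angle: float) -> np.ndarray:
    top = ens.topology
    di = top.atom_index(*spec.donor)
    ai = top.atom_index(*spec.acceptor)
    d = np.linalg.norm(ens.frames[:, di] - ens.frames[:, ai], axis=1)
    ok = d <= max_distance
    if spec.hydrogen is not None:
        hi = top.atom_index(*spec.hydrogen)
        u = ens.frames[:, di] - ens.frames[:, hi]
        v = ens.frames[:, ai] - ens.frames[:, hi]
        cosang = (u * v).sum(axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        ok &= ang >= min_angle
    return ok


def hbond_occupancy(ensembles, pairs: list[HBondSpec],
                    max_distance: float = 3.5, min_angle: float = 120.0,
                    block_length: float = 10000.0) -> OccupancyTable:
    """Per-bond occupancy (%) with block-averaged uncertainties.

    ``ensembles`` is one Ensemble or a list of them (independent
    trajectories). Occupancy is the percentage of frames satisfying the
    geometric criteria; the per-trajectory uncertainty comes from the
    spread of consecutive-block means (default block length 10 ns =
    10000 ps), and with several trajectories the reported SEM is the
    standard error over the per-trajectory occupancies.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    labels = [s.label() for s in pairs]
    per_traj = np.empty((len(ensembles), len(pairs)))
    block_sems = np.empty((len(ensembles), len(pairs)))
    for t, ens in enumerate(ensembles):
        if ens.times is not None:
            duration = ens.duration()
            if block_length > duration:
                raise ValueError("block length exceeds trajectory duration")
            n_blocks = max(int(duration // block_length), 1)
        else:
            n_blocks = min(10, ens.n_frames)
        for b, spec in enumerate(pairs):
            ind = _bond_indicator(ens, spec, max_distance, min_angle)
            per_traj[t, b] = 100.0 * ind.mean()
            blocks = np.array_split(ind.astype(float), n_blocks)
            means = np.array([100.0 * blk.mean() for blk in blocks])
            if n_blocks > 1:
                block_sems[t, b] = means.std(ddof=1) / math.sqrt(n_blocks)
            else:
                block_sems[t, b] = 0.0
    occ = per_traj.mean(axis=0)
    if len(ensembles) > 1:
        sem = per_traj.std(axis=0, ddof=1) / math.sqrt(len(ensembles))
    else:
        sem = block_sems[0]
    return OccupancyTable(labels, occ, sem, block_length, per_traj)


def basepair_occupancy(table: OccupancyTable,
                       pair_members: dict[str, list[str]]) -> OccupancyTable:
    """Collapse hydrogen-bond occupancies into base-pair occupancies.

    The pair value is the mean over its member hydrogen bonds; the SEM
    propagates as sqrt(sum SEM_i^2) / k for k members.
    """
    labels, occ, sem = [], [], []
    for pair, members in pair_members.items():
        if not members:
            raise ValueError(f"base pair {pair!r} has no member bonds")
        idx = [table.labels.index(m) for m in members]
        k = len(idx)
        labels.append(pair)
        occ.append(float(table.occupancy[idx].mean()))
        sem.append(float(np.sqrt((table.sem[idx] ** 2).sum()) / k))
    return OccupancyTable(labels, np.array(occ), np.array(sem),
                          table.block_length)
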