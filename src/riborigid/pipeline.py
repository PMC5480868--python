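"""End-to-end pipeline wiring: configuration, staging, output tables.

Two entry points mirror the two halves of the analysis. The rigidity
pipeline turns four condition ensembles (wildtype/mutant x with/without
ligand constraints) into p_lrc profiles, ligand-difference profiles and a
cooperativity table; the trajectory pipeline computes RMSF, core
selection, RMSD, radius of gyration, RAC, PCA, Mg2+ hydration and the
ion occupancy grid from one coordinate ensemble. Every output file header
records the configuration hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .model import (Ensemble, Structure, assign_regions, read_ensemble,
                    read_region_table, read_structure)
from .network import add_ligand_constraints, build_network
from .stats import (coop, coop_ttest, decompose_ensemble, delta_plrc,
                    plrc_profile)
from .synthetic import (filter_hbond_bars, make_toy_aptamer,
                        toy_snapshot_network)
from . import trajectory as tm

CONDITIONS = ("apo_apt", "lig_apt", "apo_loop", "lig_loop")


@dataclass
class PipelineConfig:
    """Validated configuration for both pipelines.

    ``inputs`` maps condition names (apo_apt/lig_apt/apo_loop/lig_loop)
    to multi-model PDB paths for the rigidity pipeline, or holds a single
    ``trajectory`` path for the metrics pipeline. ``synthetic`` switches
    to the built-in miniature-aptamer generators (no files needed).
    """

    inputs: dict = field(default_factory=dict)
    synthetic: bool = False
    n_snapshots: int = 60
    n_trajectories: int = 3
    e_cut: float = -0.6
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    region_table: str | None = None
    include_mg: bool = True
    ligand_constraints: bool = True
    binding: tuple = (47, 51, 74)
    snapshot_stride: int = 1
    block_length: float = 10000.0
    discard: float = 50000.0
    frame_spacing: float | None = None
    seed: int = 0
    outdir: str = "riborigid_out"

    _KNOWN = None

    def __post_init__(self):
        if self.e_cut >= 0:
            raise ValueError("e_cut must be negative")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be >= 1")
        if self.n_snapshots < 1 or self.n_trajectories < 1:
            raise ValueError("ensemble sizes must be positive")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__ if not
                 f.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "binding" in data:
            data["binding"] = tuple(data["binding"])
        return cls(**data)

    def config_hash(self) -> str:
        data = asdict(self)
        data.pop("outdir", None)    # where results go is not a parameter
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header(self) -> str:
        return (f"# riborigid {_version}  config={self.config_hash()}  "
                f"seed={self.seed}  e_cut={self.e_cut}  "
                f"written={time.strftime('%Y-%m-%d')}\n")


def _write_frame(df, path: Path, cfg: PipelineConfig):
    with open(path, "w") as fh:
        fh.write(cfg.header())
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# rigidity pipeline
# ---------------------------------------------------------------------------

def _synthetic_condition_results(cfg: PipelineConfig):
    """Toy-aptamer snapshot networks for the four conditions; the lig
    conditions are the same snapshots with ligand constraints added."""
    st, regions = make_toy_aptamer()
    results = {}
    for vk, variant in (("apt", "apt"), ("loop", "loop")):
        apo_tr, lig_tr = [], []
        for t in range(cfg.n_trajectories):
            rng = np.random.default_rng(
                [cfg.seed % (2 ** 31), 7 + t, 0 if variant == "apt" else 1])
            apo, lig = [], []
            for _ in range(cfg.n_snapshots):
                net = toy_snapshot_network(st, variant, rng)
                apo.append(filter_hbond_bars(net, cfg.e_cut))
                if cfg.ligand_constraints:
                    lig.append(filter_hbond_bars(
                        add_ligand_constraints(net), cfg.e_cut))
            apo_tr.append(decompose_ensemble(apo, cache=False))
            if cfg.ligand_constraints:
                lig_tr.append(decompose_ensemble(lig, cache=False))
        results[f"apo_{vk}"] = apo_tr
        if cfg.ligand_constraints:
            results[f"lig_{vk}"] = lig_tr
    return st, results


def _pdb_condition_results(cfg: PipelineConfig):
    results = {}
    topology = None
    for condition, path in cfg.inputs.items():
        topology = read_structure(open(path).read().split("ENDMDL")[0]
                                  + "ENDMDL\nEND\n")
        ens = read_ensemble(topology, path,
                            frame_spacing=cfg.frame_spacing,
                            discard=cfg.discard if cfg.frame_spacing
                            else 0.0)
        nets = []
        for k, st in enumerate(ens.structures()):
            if k % cfg.snapshot_stride:
                continue
            net = build_network(st, e_cut=cfg.e_cut,
                                include_mg=cfg.include_mg)
            if condition.startswith("lig"):
                net = add_ligand_constraints(net, set(cfg.binding))
            nets.append(net)
        results[condition] = [decompose_ensemble(nets)]
    return topology, results


def run_rigidity_pipeline(cfg: PipelineConfig) -> dict:
    """Networks -> decompositions -> p_lrc -> delta p_lrc -> Coop tables.

    Returns the result objects; tables are written under ``cfg.outdir``.
    With only some conditions available, the pipeline computes what it
    can (p_lrc always; Coop only with all four conditions).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.synthetic:
        topology, results = _synthetic_condition_results(cfg)
    else:
        topology, results = _pdb_condition_results(cfg)

    ids = topology.nucleotide_ids()
    profiles = {}
    for condition, trajs in results.items():
        prof = plrc_profile(trajs, nucleotide_ids=ids, condition=condition)
        profiles[condition] = prof
        _write_frame(prof.to_frame(), out / f"plrc_{condition}.tsv", cfg)

    bundle = {"profiles": profiles}
    for variant in ("apt", "loop"):
        lig, apo = f"lig_{variant}", f"apo_{variant}"
        if lig in profiles and apo in profiles:
            d = delta_plrc(profiles[lig], profiles[apo])
            bundle[f"delta_{variant}"] = d
            _write_frame(d.to_frame(), out / f"delta_plrc_{variant}.tsv",
                         cfg)
    if all(c in profiles for c in CONDITIONS):
        c = coop(profiles["lig_apt"], profiles["apo_apt"],
                 profiles["lig_loop"], profiles["apo_loop"])
        c = coop_ttest(c, df=max(cfg.n_trajectories - 1, 1))
        bundle["coop"] = c
        _write_frame(c.to_frame(), out / "coop.tsv", cfg)
    else:
        import warnings
        warnings.warn("not all four conditions present; Coop skipped",
                      stacklevel=2)
    return bundle


# ---------------------------------------------------------------------------
# trajectory pipeline
# ---------------------------------------------------------------------------

def run_traj_metrics(cfg: PipelineConfig,
                     ensembles: list[Ensemble] | None = None) -> dict:
    """RMSF -> core selection -> RMSD / Rg / RAC / PCA / hydration / grid.

    ``ensembles`` may be passed directly (e.g. from the synthetic
    generator); otherwise ``cfg.inputs['trajectory']`` names a multi-model
    PDB. The discard window is applied once, on read.
    """
    import pandas as pd

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if ensembles is None:
        path = cfg.inputs.get("trajectory")
        if path is None:
            raise ValueError("no trajectory input configured")
        topology = read_structure(open(path).read().split("ENDMDL")[0]
                                  + "ENDMDL\nEND\n")
        ens = read_ensemble(topology, path,
                            frame_spacing=cfg.frame_spacing,
                            discard=cfg.discard if cfg.frame_spacing
                            else 0.0)
        ensembles = [ens]
    top = ensembles[0].topology
    table = (read_region_table(cfg.region_table)
             if cfg.region_table else None)
    regions = assign_regions(top, table)

    prof = tm.rmsf(ensembles)
    core = tm.select_core(prof)
    rmsf_df = pd.DataFrame({"nucleotide": prof.nucleotide_ids,
                            "rmsf": prof.rmsf, "sem": prof.sem(),
                            "in_core": [i in set(core.nucleotide_ids)
                                        for i in prof.nucleotide_ids]})
    _write_frame(rmsf_df, out / "rmsf.tsv", cfg)

    rows = []
    for k, ens in enumerate(ensembles):
        rmsd = tm.rmsd_series(ens, fit_nucleotides=core.nucleotide_ids)
        rg = tm.radius_of_gyration(ens, regions)
        rows.append({"trajectory": k, "rmsd_mean": rmsd.mean(),
                     "rg_mean": rg.mean()})
    _write_frame(pd.DataFrame(rows), out / "global_metrics.tsv", cfg)

    racc = tm.rac(ensembles[0])
    _write_frame(pd.DataFrame({"window": racc.window, "rac": racc.rac}),
                 out / "rac.tsv", cfg)
    pca = tm.pca_project(ensembles)
    _write_frame(pd.DataFrame({"component": np.arange(1, len(
        pca.eigenvalues) + 1), "eigenvalue": pca.eigenvalues,
        "explained": pca.explained}), out / "pca.tsv", cfg)
    hyd = tm.mg_hydration(ensembles[0])
    _write_frame(pd.DataFrame({"frame": np.arange(len(
        hyd.hexahydrated_per_frame)),
        "hexahydrated": hyd.hexahydrated_per_frame}),
        out / "hydration.tsv", cfg)
    grid = tm.occupancy_grid(ensembles[0])
    grid.to_text(out / "mg_grid.txt")
    return {"rmsf": prof, "core": core, "rac": racc, "pca": pca,
            "hydration": hyd, "grid": grid, "regions": regions}
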