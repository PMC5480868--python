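"""Trajectory metrics on a synthetic miniature-aptamer ensemble.

Simulates a Gaussian-fluctuation trajectory with a prescribed per-region
mobility pattern, a two-state hydrogen bond and one hexahydrated ion,
then runs the standard analyses: RMSF with 80%-core selection, RMSD,
radius of gyration omitting P1, RAC, and hydrogen-bond occupancy with
block-averaged uncertainty.
"""

import numpy as np

from riborigid.stats import HBondSpec, hbond_occupancy
from riborigid.synthetic import (IonSpec, TelegraphBond, TrajectorySpec,
                                 make_toy_aptamer, simulate_trajectory)
from riborigid.trajectory import (mg_hydration, rac, radius_of_gyration,
                                  rmsd_series, rmsf, select_core)

st, regions = make_toy_aptamer()
spec = TrajectorySpec(
    sigma_by_region={"P2": 0.15, "P3": 0.15, "J2/3": 0.8, "P1": 0.5},
    sigma_default=0.3,
    hbonds=[TelegraphBond((34, "N1"), (65, "N1"), on_fraction=0.7)],
    ions=[IonSpec((5.0, 5.0, 10.0), "fixed")],
    n_frames=300, frame_spacing=20.0)
ens = simulate_trajectory(st, spec, seed=7, regions=regions)

prof = rmsf(ens)
core = select_core(prof, 0.8)
print(f"RMSF: P2 mean {np.mean([prof.value(i) for i in regions.members('P2')]):.2f} A, "
      f"J2/3 mean {np.mean([prof.value(i) for i in regions.members('J2/3')]):.2f} A "
      "(matches the designed mobility ordering)")
print(f"core selection: {len(core)} of 67 nucleotides "
      "(the 80% least-fluctuating set)")

rmsd = rmsd_series(ens, fit_nucleotides=core.nucleotide_ids)
rg = radius_of_gyration(ens, regions)
print(f"mean RMSD after core fit: {rmsd.mean():.2f} A")
print(f"mean radius of gyration (P1 omitted): {rg.mean():.2f} A")

curve = rac(ens)
print("RAC(w):", ", ".join(f"w={w}: {v:.2f}"
                           for w, v in zip(curve.window, curve.rac)))

occ = hbond_occupancy(ens, [HBondSpec((34, "N1"), None, (65, "N1"))],
                      block_length=1000.0)
print(f"telegraph H-bond occupancy: {occ.occupancy[0]:.1f} +- "
      f"{occ.sem[0]:.1f} % (designed stationary fraction 70%)")

hyd = mg_hydration(ens)
print(f"hexahydrated ions per frame: "
      f"{hyd.hexahydrated_per_frame.mean():.2f}")
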