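"""Recovering a designed cooperativity from four-condition ensembles.

The Coop statistic compares the joint stabilising effect of tertiary
loop interactions and ligand binding on a nucleotide against the sum of
their separate effects:

    Coop = ln[(p_lig^apt * p_apo^loop) / (p_apo^apt * p_lig^loop)]

Here the four conditions are simulated as Bernoulli ensembles whose
largest-rigid-cluster membership probabilities are set by design, so the
analytic answer is known exactly and the whole pipeline (pebble game ->
p_lrc -> Coop with propagated SEM and t-test) must recover it.
"""

from riborigid.stats import coop_ttest
from riborigid.synthetic import CoopDesign, estimate_coop

design = CoopDesign(q_lig_apt=0.9, q_apo_apt=0.6,
                    q_lig_loop=0.7, q_apo_loop=0.5,
                    n_snapshots=1000, n_trajectories=3, seed=42)
res, profiles = estimate_coop(design)
res = coop_ttest(res, df=design.n_trajectories - 1)

print(f"analytic Coop  = {design.analytic_coop:+.4f}")
print(f"estimated Coop = {res.value(15):+.4f} +- {res.sem[0]:.4f} "
      f"(t = {res.t[0]:.2f}, p = {res.p_value[0]:.3f}, "
      f"class {res.stars[0]})")
for condition, prof in profiles.items():
    print(f"  p_lrc({condition:8s}) = {prof.value(15):.3f}  "
          f"(designed {design.q_of(condition):.2f})")

# Coop > 0 means the two interactions together stabilise the focal
# nucleotide more than additively; with 3 x 1000 snapshots the estimate
# lands within a few hundredths of the designed value.
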