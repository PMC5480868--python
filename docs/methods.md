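# Methods

This note documents the models, conventions and design choices behind
`riborigid`, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic test beds do and do not show.

## Constraint-network representation

A structure becomes a body–bar multigraph. Every heavy atom is one body
with six degrees of freedom; hydrogens are absorbed into the heavy atom
they are bonded to. Bars:

| interaction | bars | criterion |
|---|---|---|
| rotatable covalent bond | 5 | single bonds (backbone, sugar, glycosidic) |
| locked covalent bond | 6 | bonds inside the conjugated nucleobase (ring and exocyclic carbonyl/amino) |
| hydrogen bond / salt bridge | 5 | detected geometrically, filtered by energy |
| hydrophobic tether | 2 | C/S pair with surface gap ≤ 0.25 Å beyond summed vdW radii |
| Mg²⁺ coordination | 5 | Mg–water-O or Mg–RNA(N/O) within 3.5 Å |
| ligand stand-in | 6 | pairwise between binding nucleobases |

All multiplicities and cutoffs are configurable (`NetworkConfig`).
Covalent connectivity comes from internal residue templates for A/C/G/U
plus inter-residue O3′–P links, with a <1.8 Å distance fallback only for
unrecognised residues; this is more robust for crystal structures with
close contacts than global distance inference.

Hydrogen bonds require donor–acceptor distance ≤ 3.5 Å and
D–H⋯A angle ≥ 120°. The energy is a Mayo-style 12–10 well,
E = 8·[5(2.8/R)¹² − 6(2.8/R)¹⁰]·cos²θ kcal/mol (θ the deviation from
linearity; squared once more for sp3–sp3 pairs), clamped at short range;
ideal geometry gives −8 kcal/mol. Only bonds with E ≤ E_cut (default
−0.6 kcal/mol; −1.0 as a sensitivity setting) contribute bars. Salt
bridges get a fixed −10 kcal/mol so they pass any attractive cutoff.
Structures without hydrogens get template-ideal polar hydrogens
(in-plane for ring and amino nitrogens, anti to the bonded neighbour for
hydroxyls); placement is logged.

Waters are kept only inside the first shell (≤ 3.5 Å) of an Mg²⁺ ion.
Mg–shell and Mg–RNA contacts are covalent-strength bars; shell-water to
RNA contacts enter as hydrogen bonds — geometrically detected when the
water carries hydrogens, by the distance criterion with a strong default
energy (−3 kcal/mol) for crystal waters that do not.

A bound ligand is modelled without ligand atoms: six bars between the
base N1 bodies of each pair of binding nucleotides (default {47, 51,
74}). Each nucleobase is internally rigid (locked ring bonds), so six
bars per pair are exactly enough to make the three bases one rigid
cluster; the operation is additive and idempotent. This is deliberately
a weak coupling — no stacking or triple-base constraints — so measured
effects are lower bounds on what a full ligand model would give.

## Rigidity analysis

The (6,6) pebble game runs on the body-bar multigraph: each body holds
six pebbles, a bar is independent exactly when seven pebbles can be
gathered on its endpoints, and placing it pays one pebble. After all
bars are processed, a failed virtual seventh-pebble test between two
bodies proves mutual rigidity, and the set visited by the failed search
is precisely the rigid cluster, giving a near-linear decomposition.
Bars are processed in a canonical sorted order; the underlying matroid
makes the independent count and the partition order-independent, which
the test suite asserts by shuffling.

Floppy modes are reported per connected component as 6V − 6 −
(independent bars) and summed; the global six rigid-body motions are
subtracted once per component. The largest cluster ties break toward
the cluster containing the smallest body index — a pure determinism
device; real inputs do not tie.

Validation is by construction: a generic rigidity-matrix rank oracle
(random generic placements and attachment points, one row per bar,
singular values below 10⁻⁸ of the largest treated as zero, two seeds
with the maximum taken) must agree bar-for-bar and cluster-for-cluster
on random networks. The acceptance suite requires 100 % agreement on
100 random networks of up to 8 bodies with multiplicities 1–6.

## Ensemble statistics

p_lrc(i) is the fraction of snapshots whose largest rigid cluster
contains the base N1 body of nucleotide i; its uncertainty is the
standard error over independent trajectories (three in the standard
design), not a binomial error — consecutive snapshots are correlated
and the trajectory spread absorbs that. Δp_lrc is the element-wise
ligand-minus-apo difference computed on paired snapshots (the lig
network is the apo network plus ligand bars, so conformational effects
cancel by construction).

Coop(i) = ln(p_lig^apt·p_apo^loop / (p_apo^apt·p_lig^loop)), referenced
to the mutant apo state, with SEM² = Σ(SEM_p/p)² over the four terms.
Zero probabilities make Coop undefined; they are reported as NaN with a
reason rather than silently padded, and an optional continuity
correction ((n₁+½)/(N+1)) is available behind a flag. The t-test of
Coop = 0 defaults to df = (number of trajectories − 1) = 2; the exact
df for this design is not canonical, so it is configurable, and the
worked value t ≈ 3.10, p ≈ 0.090 for Coop = 0.065 ± 0.021 at df = 2 is
kept in the tests as a documented reconstruction.

Occupancies are percentages of frames satisfying the geometric
hydrogen-bond criteria. Within one trajectory the uncertainty comes
from means of consecutive 10-ns blocks (accounting for
autocorrelation); across trajectories the reported SEM is the spread of
per-trajectory occupancies. Base-pair occupancy averages the member
bonds with SEM = √(ΣSEMᵢ²)/k.

## Trajectory metrics

All superpositions are mass-weighted least-squares fits (SVD); RMSF,
RMSD, Rg and RAC are invariant to global rotation/translation of the
input frames. RMSF is atom-averaged per nucleotide over all atoms
(heavy-only behind a flag); the 80 %-core selection takes
round(0.8·n) lowest-RMSF nucleotides (54 of 67 for the aptamer), ties
toward the lower id. Rg is mass-weighted and omits the P1 region by
default. RAC aligns frames to the reference (first post-discard frame;
a vs-average variant behind a flag), running-averages coordinates over
windows of w frames and reports the mean fitted RMSD; for white noise
against a noiseless reference RAC(w) ∝ 1/√w exactly, which is the
closed-form check. PCA pools the covariance of the selected atoms
(default phosphorus) over all trajectories after fitting to a common
reference, with per-trajectory projections exposed for overlap checks.
Mg²⁺ hydration counts water oxygens within 3.5 Å; any RNA atom within
3.5 Å flags chelation; hexahydrated means exactly six shell waters and
no chelation. The ion occupancy grid (0.4 Å spacing) counts frames per
cell after fitting frames to the reference; named-site occupancy uses a
3.0 Å radius by default (the 5 Å value used for nucleotide-proximity
comparisons is a separate parameter). χ histograms use
O4′–C1′–N9–C4 (purines) / O4′–C1′–N1–C2 (pyrimidines), 5° bins.

The 50-ns discard convention is applied once, at ensemble reading, when
time metadata (frame spacing) is available.

## Synthetic data: what it emulates, and what it does not

The synthetic module defines the study conditions for all tests.

**Fixture networks** (braced pair, hinge pair, chain, ring, seeded
random) have rigidity known by enumeration or by the rank oracle.

**The quadruple stand-in** builds the upper loop–loop base quadruple
(nucleotides 34/37/61/65) from idealised planar bases: a Watson–Crick
37:61 pair and a Hoogsteen-style 34:65 pair, joined by the two guanine
amino hydrogens (into C61 O2 and U34 O2) and an A65 amino bond into the
second lone pair of C61 O2 — seven bonds covering exactly the four
nucleotide pairs the occupancy analysis of the loop region tracks. The
layout is solved deterministically (exact dimer construction, a
seeded differential-evolution search for the inter-dimer pose — the
tetrad puckers out of plane, as a flat arrangement would clash — and a
per-base polish). The G37A/C61U mutant is produced by actual base
transplantation and loses exactly the two guanine-N2 bonds, so the
34–37 pairing vanishes while 37:61 survives with swapped polarity;
counts (7 → 5) and the vanished pair mirror the real mutant. The
stand-in is a geometric test bed, not a crystal structure: absolute
distances/angles are idealised and the mutant retains a 61–65 bond
that is strongly destabilised in the real molecule.

**The coarse miniature aptamer** has two bodies per nucleotide (a
backbone body and a base body) over the full 15–81 topology with the
three helices, both loops and all joining strands. Backbone links carry
3 bars — a deliberate coarse-graining: one body stands in for the six
backbone bodies of a real nucleotide, so the link must transmit fewer
constraints than a single covalent bond, which keeps the junction
strands flexible as they are in the full-atom network. Helices and
loops are rigid blocks (6-bar pairing and stacking edges); stochastic
tertiary contacts (the two quadruples, two P1 base-triple anchors, and
binding-site anchors at 47/51/74) carry Gaussian-drawn energies, so
bond presence follows from the energy filter and cutoff sensitivity is
exercised mechanically. The mutant draws weaker loop and binding-site
energies (the J3/1 anchor weakens most, mirroring the high mobility of
nucleotide 74 in the destabilised mutant). This machine reproduces the
qualitative contracts — largest cluster = the loop-coupled helix core,
P1 membership raised by ligand constraints, binding triplet fused only
by ligand constraints, Δp_lrc profiles robust to the cutoff — but its
terminal-P1 cooperativity is negative under the default energies: the
mutant's lower apo baseline gains proportionally more from the ligand
pathway. The quantitative Coop recovery is therefore tested on the
**Bernoulli condition design**, where a five-body always-rigid core and
a focal body attached with probability q per condition give p_lrc = q
and Coop = ln(q_la·q_al/(q_aa·q_ll)) exactly.

**Synthetic trajectories** add per-region isotropic Gaussian jitter
(closed form RMSF = σ√3), optional global rigid-body tumbling (fitting
invariance), two-state Markov hydrogen bonds with a designed stationary
on-fraction, and hexahydrated ions that stay, diffuse or shed a water
at a set frame. None of this models real dynamics — no anisotropy, no
correlated motions, no force field — so passing tests certify the
estimators and their uncertainties, not biological realism.

## Problem sizes and numerical choices

Default test-bed sizes: 1000 snapshots × 3 pseudo-trajectories per
condition for cooperativity recovery (identical networks are memoised,
so this is cheap), 50 × 3 snapshots per condition and cutoff for the
Δp_lrc robustness comparison, 100 random networks for the oracle
equivalence, 400–1000 frames for the trajectory closed forms. The rank
oracle is restricted to ≤ 60 bodies. Random numbers come from seeded
`numpy.random.Generator` instances everywhere; all generators are
deterministic given their seed, and the quadruple layout search uses a
fixed internal seed.

## Known limitations

- Only standard A/C/G/U nucleotides; no modified bases, no insertion
  codes; alternate locations resolve to the highest-occupancy conformer.
- The hydrophobic parameterisation and bar multiplicities are defaults
  in the FIRST lineage, exposed in `NetworkConfig` rather than fitted.
- Hydrogen placement is template-ideal, without optimisation of
  hydroxyl torsions; donors whose hydrogens cannot be placed are
  skipped with a warning.
- The crystal-structure checks (radius of gyration 16.1/16.3 Å;
  quadruple bond counts on 4FE5-derived structures) require
  user-supplied coordinate files under `data/`; the package does not
  download or redistribute them.
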