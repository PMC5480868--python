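# riborigid

Constraint-network rigidity and cooperativity analysis of riboswitch
aptamer ensembles.

Purine riboswitches regulate transcription through the stability of the
P1 helix of their aptamer domain: part of P1 belongs to the switching
sequence that decides between terminator and antiterminator folding. In
the guanine-sensing riboswitch (Gsw, nucleotides 15–81), two distant
events bear on P1 — formation of the tertiary loop–loop contacts between
L2 and L3 (two base quadruples), and ligand binding at the three-way
junction core (nucleotides U47, U51, C74). `riborigid` implements the
ensemble rigidity analysis that quantifies how these two interactions
act on P1, separately and together, for people who work with
conformational ensembles of riboswitch (or other RNA) structures.

## The method

Each conformation is turned into a **body–bar constraint network**:
every heavy atom is a body with six degrees of freedom (hydrogens
absorbed), covalent bonds contribute five bars (rotatable) or six
(locked, e.g. inside the conjugated nucleobases), hydrogen bonds that
pass an energy cutoff *E*<sub>cut</sub> (Mayo-style 12–10 potential,
default −0.6 kcal/mol) contribute five, hydrophobic tethers two, and
Mg²⁺–water / Mg²⁺–RNA first-shell contacts (≤ 3.5 Å) enter with
covalent strength. The **(6,6) pebble game** decomposes the network into
rigid clusters and flexible links; a brute-force generic
rigidity-matrix rank oracle validates the combinatorial algorithm.

Over an ensemble of *N* snapshots, the per-nucleotide probability of
sitting in the largest rigid cluster is

  *p*<sub>lrc</sub>(*i*) = *n*₁(*i*) / *N*,

evaluated at the base N1 atom and projected onto the nucleotide. A bound
ligand is modelled without its atoms by pairwise bars between the three
binding nucleobases, giving the ligand effect

  Δ*p*<sub>lrc</sub>(*i*) = *p*<sub>lrc</sub>(*i*)<sub>lig</sub> −
  *p*<sub>lrc</sub>(*i*)<sub>apo</sub>,

and the four-condition comparison (wildtype aptamer vs the G37A/C61U
loop mutant, each with and without ligand constraints, referenced to the
mutant apo state that lacks both interactions) yields the cooperativity

  Coop(*i*) = ln[ *p*<sub>lig</sub><sup>apt</sup> ·
  *p*<sub>apo</sub><sup>loop</sup> / ( *p*<sub>apo</sub><sup>apt</sup> ·
  *p*<sub>lig</sub><sup>loop</sup> ) ],

with SEM by error propagation from the four terms and a two-sided
one-sample *t*-test against zero. Coop(*i*) > 0 means the loop contacts
and the ligand together stabilise nucleotide *i* more than the sum of
their separate effects.

The package also provides the standard trajectory-level analyses used
alongside: RMSF with 80 %-core fitting, RMSD of substructures, radius of
gyration omitting P1, the RMSD-average-correlation (RAC) curve, PCA of
phosphorus coordinates, hydrogen-bond/base-pair occupancies with
block-averaged uncertainties, Mg²⁺ hydration/chelation tracking and ion
occupancy grids — plus a synthetic-data module that generates every
input with analytically known answers.

## Worked example

`examples/cooperativity.py` simulates four Bernoulli condition
ensembles whose largest-cluster membership probabilities are set by
design (0.9/0.6/0.7/0.5), so Coop = ln(0.45/0.42) ≈ +0.069 exactly, and
runs the full pipeline on them:

```
analytic Coop  = +0.0690
estimated Coop = +0.0748 +- 0.0354 (t = 2.11, p = 0.169, class ns)
  p_lrc(lig_apt ) = 0.908  (designed 0.90)
  p_lrc(apo_apt ) = 0.593  (designed 0.60)
  p_lrc(lig_loop) = 0.695  (designed 0.70)
  p_lrc(apo_loop) = 0.489  (designed 0.50)
```

The estimate recovers the designed cooperativity within one standard
error; with only three pseudo-trajectories the *t*-test is (correctly)
not significant at this effect size. The other scripts under
`examples/` cover the pebble game (`rigidity_basics.py`), the 7 → 5
hydrogen-bond loss of the loop mutant on the synthetic quadruple
stand-in (`quadruple_hbonds.py`), the ligand-constraint contract
(`ligand_constraints.py`) and the trajectory metrics
(`trajectory_metrics.py`).

A thin CLI wraps the same pipelines (`riborigid run-all`,
`riborigid network`, `riborigid rigidity`, `riborigid coop`,
`riborigid trajmetrics`); the library functions are the primary
interface.

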