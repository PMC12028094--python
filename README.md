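# pbflex

Protein Block flexibility analysis of protein conformational ensembles.

`pbflex` is for structural bioinformaticians who want to quantify *local*
backbone flexibility in an MD trajectory or any multi-conformation ensemble
(e.g. a kinase domain simulated apo, phosphorylated and inhibitor-bound) and
to compare systems position by position. Global metrics such as RMSF blur
local rearrangement into overall motion; encoding each frame with a
structural alphabet keeps the signal local to each residue.

## The method

Every frame is encoded as a string over the 16-letter **Protein Block (PB)**
alphabet (labels *a*..*p*; *m* is the α-helix core prototype, *d* the central
β-strand). Each residue *i* is described by the 8 backbone dihedrals of its
5-residue window (ψ<sub>i−2</sub>, φ<sub>i−1</sub>, ψ<sub>i−1</sub>,
φ<sub>i</sub>, ψ<sub>i</sub>, φ<sub>i+1</sub>, ψ<sub>i+1</sub>,
φ<sub>i+2</sub>) and assigned the prototype with the smallest RMSDA (root
mean square deviation of angles, with periodic wrapping). The two first and
two last residues of a chain have incomplete windows and get `Z`.

From the per-position PB frequencies *f<sub>x</sub>* over frames:

- **N_eq** = exp(−Σ<sub>x</sub> *f<sub>x</sub>* ln *f<sub>x</sub>*) — the
  equivalent number of PBs, from 1 (one PB only: rigid) to 16 (uniform:
  random coil / disorder). Positions are binned into six flexibility
  categories: rigid (N_eq = 1), quite rigid (1–2], moderate (2–4],
  flexible (4–6], extremely flexible (6–8], disordered (8–16].
- **ΔPB** = Σ<sub>x</sub> |*f*¹<sub>x</sub> − *f*²<sub>x</sub>| — the L1
  distance between two systems' PB distributions at a position, from 0
  (identical composition) to 2 (disjoint); ΔPB/2 is the fraction of PB
  assignments that differ.
- **ΔN_eq** = |N_eq¹ − N_eq²| — the entropy change, which ΔPB complements
  because different PB compositions can share one entropy.
- Classical **RMSF** (Cα fluctuation about the mean structure, optionally
  after superposition) and per-frame **RMSD** to the starting frame, plus
  Pearson correlations between N_eq, RMSF and crystallographic B-factors.

Because the MD ensembles such studies rest on are rarely redistributable,
the package includes a first-class synthetic generator: template-mixture
dihedral sampling with known mixture weights (the expected N_eq is the
exponential entropy of the weights), internal-coordinate chain building
whose torsions round-trip exactly, and Gaussian positional ensembles whose
unfitted RMSF converges to σ√3.

## Worked example

`examples/04_ground_truth_recovery.py` draws a noise-free 75/25
helix/strand mixture (4000 frames, exact counts), rebuilds 3D backbones,
and runs the full pipeline:

```
frames per template: [3000, 1000] (weights (0.75, 0.25))
closed-form N_eq of the weights: 1.754765350603
pipeline N_eq at mixed positions: 1.754765350603
max |pipeline - closed form| at discriminating positions: 0.00e+00
```

Every position where the two templates use different PBs recovers
exp(−0.75 ln 0.75 − 0.25 ln 0.25) ≈ 1.7548 exactly. Comparing that mixture
against a helix-locked system (`examples/03_compare_systems.py`) gives

```
region  start  end  mean_delta_pb  max_delta_pb  mean_delta_neq  max_delta_neq
  core      5   11          0.580         0.580           0.826          0.826
```

— a ΔPB of 0.58, i.e. 29% of the PB assignments at those positions differ
between the flexible and the rigidified system.

The other examples cover PB string assignment (`01`), single-system
flexibility profiles (`02`), and the `pbflex` command line (`assign`,
`profile`, `compare`, `simulate`, `report` subcommands) mirrors the same
stages for shell use.

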