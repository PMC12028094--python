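# Methods

## Scope and model

`pbflex` quantifies local backbone flexibility of a protein conformational
ensemble by structural-alphabet encoding. The model has three layers:

1. **Geometry.** Backbone dihedrals are measured with the IUPAC sign
   convention (cis = 0°, trans = 180°), reported in (−180, 180] with exact
   ±180 mapped to +180: φ<sub>i</sub> = torsion(C<sub>i−1</sub>, N<sub>i</sub>,
   CA<sub>i</sub>, C<sub>i</sub>), ψ<sub>i</sub> = torsion(N<sub>i</sub>,
   CA<sub>i</sub>, C<sub>i</sub>, N<sub>i+1</sub>). Chain termini and any
   position adjacent to a residue missing N/CA/C are undefined (NaN), never
   silently filled.
2. **Encoding.** Each residue's 5-residue window of 8 dihedrals is matched
   to the nearest of the 16 Protein Block prototypes under RMSDA: the root
   mean square of the angle differences wrapped into [−180, 180]. Window
   angles are weighted uniformly (the classic variant). Exact RMSDA ties
   break toward the first label in a..p order — a measure-zero event kept
   deterministic. Unassignable positions (incomplete windows, the two
   first/last residues) carry `Z` and are excluded from all frequency
   statistics.
3. **Statistics.** Per-position PB frequencies use only non-`Z` frames in
   the denominator; a position with no assigned frame is flagged empty
   (NaN), distinct from a zero frequency. N_eq is the exponential Shannon
   entropy with natural log and 0·ln 0 := 0. ΔPB is the L1 distance between
   frequency vectors; its printed companion interpretation is ΔPB/2 = the
   fraction of differing PB assignments. Correlations between N_eq, RMSF
   and B-factors use Pearson's r with pairwise deletion of undefined
   positions; constant series give an undefined marker (NaN), not an error.

## Reference table

The 16×8 prototype dihedral matrix is the canonical published table of the
PB alphabet, shipped as `data/pb_reference_angles.csv` and validated on load
against an SHA-256 checksum, a 16×8 shape check and an angle-range check.
It is a fixed constant of the method, not a fitted object; no two rows are
closer than 1° RMSDA.

## Flexibility categories

N_eq maps to six categories: *rigid* is reserved for N_eq numerically equal
to 1 (within ε = 1e−6), because a position showing literally one PB is
qualitatively different from one at N_eq = 1.01; above that the bins are
half-open: (1, 2] quite rigid, (2, 4] moderate, (4, 6] flexible, (6, 8]
extremely flexible, (8, 16] disordered. A two-threshold variant exists in
the literature (very flexible above 6, disordered above 8); it is subsumed
by the upper bins and not separately implemented. Values outside
[1 − ε, 16 + ε] raise, as they can only come from an upstream bug.

## RMSF / RMSD protocol

Both are computed on Cα atoms only. RMSD compares each frame to a reference
frame (default: the first) after least-squares superposition
(Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`; rotations are
proper by construction). RMSF is the fluctuation about the mean structure;
with `fit=True` (default) all frames are first superposed onto frame 0 on
Cα in one pass — no iterative mean refitting — matching common MD-suite
behaviour. The fit mode is recorded in output metadata because published
profiles rarely state it. `fit=False` uses raw coordinates, for which the
isotropic-noise expectation RMSF = σ√3 is exact and is used by the recovery
tests.

## Synthetic generator

The generator emulates the *statistical* structure of an MD ensemble, not
its physics:

- **Template mixtures.** Frames copy one of K full-length φ/ψ templates
  drawn with weights w (seeded), optionally with wrapped-Gaussian angular
  noise. Mixtures are over whole-chain templates rather than independent
  per-position PB draws because overlapping 5-residue windows make
  independent sampling geometrically inconsistent; template mixtures give
  exact, self-consistent ground truth (the frame→template record). With
  `exact_counts=True` frames are apportioned to templates by largest
  remainder (order still shuffled), so realized proportions equal the
  weights exactly and the pipeline N_eq at discriminating positions equals
  exp(−Σ w ln w) to machine precision; the default multinomial mode keeps
  sampling variability for statistical tests.
- **Chain building.** Backbones are built from dihedrals by sequential
  internal-coordinate extension (NeRF-style) with fixed constants: bond
  lengths N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; bond angles N–CA–C
  111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω fixed trans (180°). These are
  idealized constants for synthetic chains only, not a modelling claim;
  re-measuring torsions from a built chain reproduces the inputs to better
  than 1e−6°.
- **Gaussian ensembles.** Isotropic per-atom positional noise of known σ,
  whose unfitted RMSF converges to σ√3 with standard error ≈ σ/√(2n).

What the generator does **not** emulate: correlated motions, realistic
Ramachandran coupling between neighbours, side chains, solvent, or
force-field energetics. Passing recovery tests therefore demonstrates the
*analysis* is exact and unbiased under known mixtures and noise — it says
nothing about whether a given force field samples the right ensembles.

## Problem sizes

Default test and example runs use 10–50-residue chains and 20–4000 frames:
mixture recovery uses 4000 frames of a 15-residue chain, RMSF recovery 2000
frames of a 20-residue chain, round-trip checks 100 random 50-residue
series. These sizes make every closed-form check sharp (Monte-Carlo errors
well below the assertion tolerances) while keeping the full suite fast.

## Numerical and design choices

- Angles live in (−180, 180]; wrapped differences in [−180, 180]. NaN is
  the single undefined marker throughout and propagates (a window with any
  undefined angle is undefined; ΔN_eq/ΔPB with an empty side is undefined).
- The ΔPB interpretation and bounds force the absolute value inside the
  sum; without it the sum over a normalized difference is identically zero.
- Degenerate torsion input (coincident/collinear points) raises rather than
  returning NaN, so geometry bugs cannot masquerade as missing data.
- Author residue numbering is the only public coordinate system; frames
  from several files pool into one ensemble but keep a replicate tag.
  Altlocs resolve to the highest-occupancy conformer; waters, heteroatoms
  and hydrogens are dropped on read; multi-chain files require an explicit
  chain selection.
- All frames provided are used for PB statistics by default; `stride`
  subsamples when desired.
- The ΔPB flagging threshold in comparisons defaults to 0.4 — the level at
  which a composition change is conventionally called notable — and is
  configurable.
- The shipped JAK2 JH1 kinase-domain region annotation pins the printed
  bounds (G-rich loop 858–860, activation loop 1010–1015, C-helix region
  885–890) and marks interpolated bounds "(approx)"; users override with a
  TSV.

## Known limitations

- PB assignment needs φ/ψ only, but RMSF/RMSD need Cα coordinates; an
  ensemble read from dihedral-only sources supports the PB branch only.
- No statistical testing of N_eq differences is provided (ΔN_eq/ΔPB are
  descriptive), and no smoothing of profiles.
- The binary-trajectory adapter trusts the topology's residue numbering;
  renumbered topologies will misalign region annotations.
- Secondary-structure assignment (DSSP) and conformer clustering are out of
  scope.
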