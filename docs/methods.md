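# Methods

## Scope and data model

The package analyses protein structures for (potential) cation-π
interactions, proposes point substitutions that could create new ones,
screens them by persistence over conformational ensembles, and performs
the kinetic/thermodynamic calculations used to compare engineered enzyme
variants. Structures are read and written as PDB only; a multi-model PDB
is the sole ensemble format (one MODEL = one frame), with identical
residue/atom topology enforced across frames at construction — a
violation raises rather than truncating. Author residue numbering is
preserved verbatim (the literature on PG63 refers to author positions
such as His58 or Thr304). Altloc groups collapse to the
highest-occupancy conformer (ties: altloc `A`, then lexicographic);
HETATM records and waters are excluded by default. Hydrogens are kept
when present but never required: every geometric operation is defined on
heavy atoms, and for Lys without hydrogens the charged-group mass center
degenerates to the NZ position by construction.

## Cation-π geometry

The charged group is Lys NZ (plus HZ* when present, mass-weighted) or
the Arg guanidinium NE/CZ/NH1/NH2 (mass-weighted, with a least-squares
plane). Aromatic rings are the Phe/Tyr six-ring and both Trp rings; ring
centroids are unweighted means and ring normals the smallest principal
axis of the ring-atom scatter, whose sign is arbitrary — all angles are
therefore folded into [0°, 90°].

Two inclusive rules decide a pair: distance(mass center, centroid) ≤
`d_cut` (default 6.0 Å) and angle ≤ `a_cut` (default 60°). The published
criterion's "dihedral angle between the side chains" is ambiguous between
an axial angle, a plane–plane angle, and a four-atom torsion; this
package defaults to the *axial* convention (ring normal vs
centroid→cation vector) because it is defined uniformly for Lys and Arg,
and offers `angle_mode="plane_plane"` (Arg only, falling back to axial
for Lys) for the alternative reading. Neither is asserted to be the
original authors' intent. A 1e-9 guard on both comparisons keeps exact
boundary constructions (6.0 Å, 60°) from failing to floating-point noise
without affecting any physically distinguishable verdict.

Whole-structure scans pair every Lys/Arg with every Phe/Tyr/Trp at
sequence separation ≥ 2 (same chain; configurable — the i/i±1 exclusion
avoids trivial neighbour contacts). Trp counts as satisfied if either
ring passes; the reported ring is the satisfied one with the smaller
distance. Histidine is neither cation nor π by default (the design
targets are K/R/F/Y/W), switchable via `CriteriaConfig`. Residues with
missing group atoms are skipped with a warning, never fatally.

## Mutation design and screening

Enumeration: for each target (K/R/F/Y/W) and each residue with Cβ–Cβ ≤
`proximity_cut` (Cα for Gly), a candidate substitution to Tyr (cationic
target) or Lys (aromatic target) is emitted; sites already of the
requested type, already interacting with that target, or in the
user-supplied exclusion set are skipped; duplicates keep the nearest
partner. The default cutoff of 8 Å is a documented choice — the source
workflow says only "close proximity", and the exact filter that produced
its published candidate count is not recoverable — so the parameter is
exposed and echoed in every report. No catalytic-site residues are
excluded a priori; exclusions are entirely user-controlled.

Placement rebuilds the side chain from the Chemical Component
Dictionary's ideal geometry (bundled with biotite), grafted by
superposing template N/CA/C onto the site backbone; χ dihedrals are then
set exactly by rotating the downstream atoms about each χ bond. The
rotamer search is an exhaustive grid of {−60°, 60°, 180°} per χ (9
placements for Tyr, 81 for Lys) — deterministic and complete over the
staggered minima, at the cost of ignoring rotamer statistics; this is a
deliberately coarse approximation documented in lieu of a rotamer
library. A clash is any new side-chain heavy atom within `clash_cut`
(default 2.5 Å) of another residue's heavy atom. Among clash-free
rotamers the smallest cation–ring distance wins, and feasibility is that
rotamer's two-rule verdict. Placement never moves atoms outside the
mutated residue.

Occupancy screening consumes externally produced ensembles (the package
never runs molecular dynamics): occupancy = 100 × satisfied frames /
total frames, and a candidate passes only when occupancy strictly
exceeds the threshold (default 50%), so a 50.0% ensemble fails. Frames
where the pair cannot be evaluated count as unsatisfied with a warning.

## Ensemble flexibility

Superposition is the Kabsch least-squares solution (via scipy's
`Rotation.align_vectors`, proper rotation guaranteed); an independent
Monte-Carlo optimality check backs it in the tests. RMSD series are
computed per frame against a reference frame after superposition on the
selection (default Cα). RMSF uses an iteratively refined mean structure
(superpose-and-average, 2 passes, seeded from frame 0) as reference
rather than frame 1, reducing reference bias; per-residue values are the
Cα RMSF. Superposition necessarily absorbs a small share of any
localized motion into the alignment — on an N-atom selection a single
moving atom's RMSF is damped by roughly a factor (1 − 1/N) — which the
tests account for by using large static anchor sets where closed forms
are asserted.

Hydrogen-bond criteria are not stated in the source workflow; the
defaults (donor–acceptor N/O distance ≤ 3.5 Å; D–H···A angle ≥ 120°
when hydrogens are present) follow common MD-analysis practice and are
fully configurable and reported alongside every output. In
hydrogen-free structures the distance rule alone applies and records are
undirected; with hydrogens, a donor must carry an attached hydrogen.
The T3 loop 1 (90–106), T3 loop 2 (147–162) and T1 loop (269–289)
windows of the PG63 β-helix ship as named presets for report
convenience.

## Thermo-kinetics

Lineweaver–Burk (OLS on 1/S vs 1/v; Km = slope/intercept, Vmax =
1/intercept) is the primary Michaelis–Menten estimator because it is
what the characterization workflow states; an unweighted direct
nonlinear fit is provided as a clearly labelled cross-check, since the
reciprocal transform re-weights errors and the two disagree under noise.
Units are fixed per function and never converted silently: Δ(ΔG) uses
R = 8.314 J·mol⁻¹·K⁻¹ and reports kJ/mol; calorimetric ΔG⁰ = ΔH − TΔS
uses ΔH in kcal/mol and ΔS in cal·mol⁻¹·K⁻¹ (divided by 1000); the
−RT·ln Ka consistency value uses R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹ and
generally differs from ΔH − TΔS on the same record because the two
routes carry independent experimental errors.

Temperature is always an explicit argument. The published PG63 kinetic
table's Δ(ΔG) column is reproduced to 2 d.p. at T = 348 K for every
single mutant — not at the printed 50 °C assay temperature (323.15 K) —
with the triple mutant off by ≤ 0.01 kJ/mol at any single temperature.
This inconsistency of the source table is flagged, not resolved: the
package's table reproductions document and use 348 K, and
`DDG_TABLE_TEMPERATURE_K` records it as data, not as a default.

Half-life fitting is OLS of ln(activity) on time with activities
normalized to the first point; a non-negative slope is an explicit
no-decay error. T₅₀ max-normalizes the profile and linearly interpolates
the unique 0.5 crossing, erroring on none or several. Tₘₐₓ is the argmax
at the measured grid point, with no interpolation, matching how coarse
temperature grids are reported. Rounding to printed precision happens
only in comparison harnesses, never inside computations; published
difference columns are reproduced as differences of the *rounded*
values, which is how such tables are printed.

## Synthetic data: what it does and does not emulate

The generators produce the geometric and statistical *contracts* of the
real inputs, not physical realism. Pair fixtures place analytically
exact planar rings and charged groups so the measured geometry equals
the requested (distance, θ) to ~1e-9; ensembles achieve a designed
occupancy exactly, by rigidly displacing the cation residue beyond the
distance rule in `n − round(p·n)` frames and shuffling frame order by
seed; scaffolds are extended chains (φ = −120°, ψ = 130°) with ideal
backbone geometry — a deliberate simplification of the real enzyme's
parallel β-helix, adequate because the design operations only need local
realism. Noise on rate/activity tables is multiplicative Gaussian
(assay-CV interpretation), seeded via numpy's `default_rng`; identical
(parameters, seed) gives identical output. Consequently, passing tests
demonstrate correctness of the geometric rules, estimators and screen
semantics — they do not demonstrate that any particular real mutant
would show these occupancies, which requires a structural model and MD
sampling outside this package's scope.

Where a real deposited object is unavailable, a stand-in is labelled
synthetic: the 342-residue census sequence is generated with the study
enzyme's known K/R/F/Y/W composition (`make_sequence`), so the census
check exercises the counting machinery against known ground truth rather
than independently re-deriving the composition.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: two-residue
fixtures, 10–100-frame ensembles, 20–30-residue scaffolds, 100-seed
estimator ladders. The grid oracle covers d ∈ (0, 8] Å × θ ∈ [0°, 90°]
at 0.25 Å / 5° resolution. Degenerate inputs raise typed errors:
coincident cation/centroid, collinear superposition sets, non-positive
kinetic inputs, profiles without a unique 50% crossing. Ties in altloc
resolution and rotamer selection break deterministically (documented
above), so every pipeline rerun with the same inputs and configuration
is bit-identical.

## Known limitations

- No energetics: the criterion is purely geometric; no
  electrostatic/van-der-Waals scoring, no folding-ΔΔG prediction, no
  solvent-accessibility filter.
- The rotamer grid misses off-staggered conformations; feasibility is
  judged on the minimum-distance clash-free rotamer only.
- The screen's biological validity depends entirely on the supplied
  ensembles; the package neither generates nor validates MD sampling.
- PDB is the only structure format (no mmCIF, no binary trajectories);
  structures needing repair or protonation assignment must be prepared
  upstream.
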