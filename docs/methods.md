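# Methods

## The similarity model

A query (or "target") molecule — or a set of mutually aligned molecules —
defines a frame of *observer points*, each sitting at an ideal distance
γ = 4.0 Å from the nearest van der Waals surface of the target. At each
point i, six conformation- and pose-dependent values are measured for any
molecule:

| value | definition |
|---|---|
| `stc` | min over atoms of (distance − vdW radius) |
| `coul` | Coulombic energy (kcal/mol) of a +0.2 e probe at the point |
| `don`, `donθ` | surface distance to the nearest donor proton; angle point–proton–base atom |
| `acc`, `accθ` | surface distance to the nearest acceptor; angle point–acceptor–neighbor-centroid |

Angles are radians internally; 180° is ideal hydrogen-bonding geometry
(linear donor, lone pair aimed at the point).

The Coulombic feature uses a rescaled distance `d = max(r − (γ−2), 0)` so
observers feel charges as if ~2 Å from the surface, and a dielectric
`ε(r) = 1/(1 − s(r − (γ+2), 0.5))` that is 1 near the surface and grows
without bound roughly one water shell beyond γ; each atom contributes
`0.2 · 332.0716 · q / (ε(r)(d + 0.05))`. Numerically we use
`1/ε = expit(−(r − (γ+2))/0.5)`, which is exact and overflow-safe.

A subject pose is compared through Gaussians `g(x,σ) = exp(−x²/σ)` of the
feature differences. Donor and acceptor terms multiply a distance Gaussian,
an angle Gaussian, and an attention weight
`w = s((γ+2) − dₛ, α) + s((γ+2) − dₜ, α)` ∈ (0, 2) that concentrates each
observer on polar features close to it; the weight is deliberately not
renormalized — the normalization constant absorbs its scale. Each point is
further weighted by `Wᵢ = g(stcᵢˢ − γ, 2)`, which depends only on the
subject and suppresses spurious similarity at points far from a small
subject inside a large target's frame. Constants: σ_stc = 2.0,
σ_coul = 8.0, σ_da = 1.0, σ_daθ = 0.5, α_da = 0.25; the three component
classes (shape, Coulombic, donor/acceptor) carry weights of 1.0 by default
and can be ablated independently. The normalization constant C_t is the raw
self-comparison sum divided by 10, so a target scores exactly 10.0 against
itself; strain subtracts 0.05 per kcal/mol of subject conformer energy above
its ensemble's global minimum.

Molecules with no donor (acceptor) report a sentinel distance of 10⁶ Å and
angle 0; the Gaussians and attention weights then vanish smoothly, which is
the intended "absent feature" behavior and needs no special-casing in the
gradient.

**Joint queries.** For a multi-ligand target, every point stores one feature
row per constituent and the subject takes, at each point, the maximum of the
weighted component sum over constituents. C_t for a joint query is the mean
of the constituents' max-semantics self-scores divided by 10 (a perfect
mimic of the amalgam therefore scores near 10); a "first ligand" convention
is available as an argument. This is our choice — the normalization is only
defined for single-ligand queries in the underlying model.

## Observer placement

A sphere centered at the target-union centroid, with radius 8.0 Å beyond the
furthest atomic surface point, is tessellated by a deterministic spherical
Fibonacci lattice at ~1.0 Å spacing (the point count is 4πr²/s²; the
deterministic lattice makes pruning bit-reproducible). Each point is moved
along its centroid ray by (d_min − γ) and the projection is repeated ten
times; it converges to |d_min − γ| ≤ 0.05 Å on all fixtures, and points
initially inside γ move outward along the same ray. The dense set is thinned
by iterative max-min selection starting from the lowest-index point (ties
break toward the lowest index), at 2.0 Å spacing for geometric work and
4.0 Å for screening. For joint targets, the procedure is repeated per
constituent ligand and any ligand-specific point further than 2.0 Å from the
evolving set is appended, so ligands hidden inside the union still get
surface coverage; for a single-ligand target this pass would reproduce the
base set and is skipped.

## Pose search and optimization

Candidate alignments come from matching typed site triangles between subject
and target: heavy-atom ring centroids, donor protons, acceptor atoms, and
terminal heavy atoms (capped at 12 sites per molecule; the underlying method
does not publish its matched point types, so ours are config-level
constants). Triangle pairs with matching type triples and side lengths
within 0.75 Å yield least-squares rigid transforms over all orientation
correspondences, deduplicated at 0.5 Å RMSD; molecules with fewer than three
sites, or with no compatible triangles, fall back to four principal-axes
placements (the proper-rotation sign combinations).

Seeds are scored, the best K kept per conformer (10/25/50 for
pfast/pscreen/pgeom — our throughput-oriented choice), and each is refined
by BFGS on the six rigid parameters (rotation vector about the start
centroid + translation), using the analytic gradient: reverse-mode
differentiation of the per-point similarity through the feature geometry,
with argmin/argmax selections held fixed (the objective is piecewise
smooth; the gradient matches central finite differences to better than
1e-6 relative away from selection boundaries). The rotation-vector Jacobian
uses the exact closed form for d R(ω)/dω. Optimization is monotone-accept:
the returned pose never scores below its start.

`pgeom` additionally optimizes torsion deltas of rotatable bonds (acyclic
single bonds with a heavy substituent on each side, amides excluded) in
internal coordinates, with the torsion gradient taken as the rigid-rotation
generator about the current bond axis. Strain is held at the annotated
conformer energy during optimization and re-evaluated with MMFF94 afterwards
when the molecule carries a force-field handle; folding the force-field
gradient into the search objective is deliberately out of scope. Conformer
ensembles are downsampled to the mode caps (25/120/250) by greedy max-min
diversity over superposition RMSD, seeded with the global-minimum conformer.
Final poses are deduplicated at 0.25 Å heavy-atom RMSD.

## Overlap metrics and RMSD

MO is the fraction of subject atoms whose centers fall inside any target
atom sphere; DAO the fraction whose own sphere has ≥ 75% of its volume
inside a *single* target atom (analytic sphere-lens formula, clipped to
[0,1]). Both include hydrogens by default — a protruding hydroxyl proton
counts — with a heavy-atom option. Pairs are tractable when MO ≥ 0.8 or
DAO ≥ 0.5. Symmetry-corrected RMSD minimizes heavy-atom RMSD over
element- and bond-order-preserving graph automorphisms (networkx VF2,
enumeration capped at 10⁴; past the cap the minimum over the enumerated
prefix is an upper bound), with no re-superposition.

## Chemistry model

Radii are the Bondi (1964) table, shipped as a fixed asset because the
steric features subtract them. Partial charges default to Gasteiger with an
MMFF94 option ("keep" preserves file charges); the choice is explicit
because similarity quality depends on it. Donor/acceptor perception is a
small valence-rule table: any H on N/O/S donates; O with ≤ 2 neighbors
accepts; N accepts only with ≤ 2 neighbors and non-positive formal charge.
This excludes amide and sp3 amine nitrogens — the former correctly (the
2-pyrrolidone panel molecule must show exactly one acceptor, its carbonyl
oxygen), the latter as a deliberate simplification for conjugation-ambiguous
cases; the rule table is exposed for override. MOL2 (TRIPOS) has a
hand-rolled reader/writer because no installed library writes SYBYL MOL2
with charges; SD files go through RDKit with charges and conformer energies
in `PARTIAL_CHARGES` / `E_REL_KCAL` tags. SD V2000 coordinates carry four
decimals, so SD round trips are exact to 1e-4 Å (MOL2 to 1e-6).

## Synthetic data

The fixture module regenerates everything from SMILES + seeded ETKDG
embedding + MMFF94 (UFF fallback) minimization, bit-identically per seed.
The screening library emulates a property-matched active/decoy design at toy
scale: actives are near-copies of the query (0.08 Å coordinate jitter,
sign-preserving 10% charge noise) so polar geometry and field signs survive;
decoys are isosteres, half with fully permuted partial charges (wrong field,
intact hydrogen bonding) and half with donor/acceptor character removed and
a single heavy-atom charge swap (wrong hydrogen bonding, mildly wrong
field). Every molecule is delivered in a randomized rigid pose. By
construction each decoy is deficient in at least one similarity component
while no single component sees every deficiency, so the full function
separates actives from decoys while each single-component ablation does
measurably worse — mirroring, at desk scale, the direction of the
full-benchmark component experiments. What this does *not* show: real
decoys differ topologically from actives, real actives are not conformers
of the query, and enrichment values on this library (AUC ≈ 1 for the full
function) say nothing quantitative about large-benchmark performance.

Overlap-pair fixtures build the two tractability regimes directly: a jittered
copy (high DAO) and an in-plane rotated copy whose atom centers stay inside
the target volume while atom-to-atom correspondence is destroyed (high MO,
low DAO); both are verified at generation time.

## Problem sizes and numerical choices

Tests and the acceptance script run on the small-molecule panel (9–15
atoms), 50-trial pose-recovery batches, and the 20-active/200-decoy library;
these sizes were chosen so the full suite completes in a couple of minutes
on one core while still exercising every code path. The sphere-lens
acceptance check compares against a 2²⁰-sample scrambled-Sobol Monte-Carlo
estimate, whose own error (~1e-4) is far below the 1e-3 comparison band —
a plain pseudo-random estimate at that sample count would have σ ≈ 5e-4 and
the comparison would be dominated by estimator noise. Angle gradients floor
sin θ at 1e-8, which zeroes the gradient smoothly at exact collinearity.
Screens never abort on a bad record: failures are logged and scored −∞.

## Known limitations

- No Cartesian all-atom optimization mode; internal coordinates only.
- No conformer generation beyond the fixture embedding fallback; ensembles
  and their energies are inputs.
- No protein-pocket superposition; overlap metrics assume pre-aligned poses.
- Donor/acceptor typing is a deliberate simplification (no thioether or
  sp3-amine acceptors, no tautomer awareness).
- Imprint ranking recomputes alignments per basis molecule; it is the
  accuracy baseline, not the optimized disk-bound indexing variant.
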