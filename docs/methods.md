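# Methods

## The descriptor

A spectrophore condenses the three-dimensional property fields of one
molecular conformation into a fixed-length vector of interaction energies
with a set of artificial "receptors". Each receptor is a rectangular cage
around the molecule whose 12 box-edge midpoints carry values P(c, i) ∈
{+1, −1} summing to zero (six of each sign). For a conformation with atoms
*j* carrying property values A(j, p), the interaction with cage *c* is

    V(c, p) = −100 · Σ_i Σ_j A(j, p) · P(c, i) / r_ij ,

with r_ij the Euclidean distance (Å) between cage point *i* and atom *j*.
The −100 factor scales values to order one and makes attractive interactions
positive. The molecule is centred on its centre of geometry and rotated
through a full Euler grid; V is evaluated at every orientation, with the box
rebuilt each time so that the molecule-to-cage distance stays at the
*resolution*; the per-(cage, property) maximum over all orientations is
kept. Blocks are ordered property-major — charges, lipophilicities, shape
deviations, electrophilicities — each block in cage-table order, giving
4 × 12 = 48 values with the default cage set (72 for the stereospecific set,
120 for both).

## Cage sign patterns and their classification

Under the 24 proper rotations of the cage (which permute the 12 edge
midpoints), the 924 sum-zero sign patterns fall into 48 orbits: 12 orbits
are equivalent to their own inversion image ("non-stereospecific") and the
remaining 36 form 18 chiral pairs ("stereospecific"). The packaged table
(`data/cages.tsv`) ships one representative per class: the 12
non-stereospecific patterns and one member of each of the 18 chiral pairs.
`validate_cage_set` verifies sum-zero, the six/six balance, pairwise
distinctness, and the inversion classification *modulo rotations* — no slot
pairing makes the patterns literally centrosymmetric; the physically
meaningful notion is equivalence modulo the rotations the engine maximizes
over.

The slot→edge assignment (documented in `cage_model`) is the unique one, up
to cage rotation, under which the shipped table is internally consistent:
all 12 non-stereospecific rows land in the 12 distinct inversion-closed
classes and the 18 stereospecific rows cover all 18 chiral pairs exactly
once. The provenance of the one corrected table row is documented in the
data file's header.

## Atomic properties

* **EEM partial charges.** Electronegativity equalization: all atoms share
  one molecular electronegativity μ, giving the linear system
  χ_i + 2η_i·q_i + Σ_{j≠i} q_j/(κ·r_ij) = μ under Σq_i = total formal
  charge. The packaged χ/η calibration (`data/atomic_parameters.tsv`)
  is used with distances in Bohr, i.e. κ = 1/a₀ = 1.8897 Å⁻¹ (the
  `BOHR_PER_ANGSTROM` constant, overridable per call); this scale reproduces
  the reference EEM charges of Open Babel's `eem` model to the printed
  precision on small test molecules. Coincident atoms make the system
  singular and are rejected with the offending atom pair named.
* **EEM electrophilicities.** The published descriptor names this property
  without printing a formula. Here it is *defined* as the per-atom share of
  one added positive unit charge, e_i = q_i(Q+1) − q_i(Q), which by
  linearity is the EEM solve with zero electronegativity vector and total
  charge 1 (the EEM Fukui-type response). It is well-posed, linear and
  normalized (Σe_i = 1). This is an interpretation; other implementations
  use different (also unpublished) definitions.
* **Lipophilicities.** Rule-based per-element contributions. Hydrogen
  splits into an apolar row (all neighbours in {C, H}) and a polar row
  (anything else); a hydrogen with no recorded neighbours is conservatively
  treated as polar. Eleven metals/metalloids share one row; unknown elements
  take a total fallback row.
* **Shape deviations.** Signed deviation d_i − mean(d) (Å) of each atom's
  distance to the centre of geometry from the average molecular radius;
  sums to zero by construction. `signed=False` gives |d_i − mean(d)| for
  cross-checks against implementations that fold or rescale the sign (the
  choice only rescales/reflects the shape block; the reference Open Babel
  code, for instance, additionally divides by the mean radius).

## Adjustable parameters

| parameter | default | meaning |
|---|---|---|
| accuracy | 20° | Euler-grid angular step; restricted to {1, 2, 5, 10, 15, 20, 30, 36, 45, 60}° |
| resolution | 3 Å | minimum molecule-to-cage distance (> 0), the range of a non-bonded ligand–receptor contact |
| stereospecificity | `none` | cage set: `none` (12), `unique` (18), `all` (30) |
| normalization | `none` | per-property-block post-processing: `none`, `mean`, `std`, `all` |

Normalization operates per property block with the population
(n-denominator) standard deviation; a block with spread below 1e−12 is left
unscaled with a warning. Larger resolutions shrink all magnitudes
(the cage is further away), so spectrophores are only comparable at
identical settings; the similarity operations refuse mixed settings rather
than rescaling.

## Numerical and design choices

* **Rotation grid.** R(α, β, γ) = Rz(γ)·Ry(β)·Rx(α), every angle over
  {0, step, …} < 360°, identity first, first orientation attaining the
  maximum kept. The parameterization is redundant; only the maximum
  matters. The grid is exactly closed under pre-rotation of the molecule
  about x by multiples of the step — the grid-aligned rotation invariance
  in the tests. It is *not* closed under arbitrary 90° moves, so the
  remaining invariances are asymptotic in the step (below).
* **Shared-work evaluation.** Per orientation, one 12 × n_atoms distance
  matrix serves all cages and all four properties
  (V = −100·P·(1/R)·A as a pair of matrix products); orientations are
  processed in chunks of ≈ 2·10⁶/(12·n_atoms) to bound memory. A naive
  orientation-by-orientation, cage-by-cage reimplementation in pure Python
  agrees to ≲ 1e−13 and serves as the test oracle.
* **Box.** Axis-aligned, per-axis min/max of the rotated coordinates ±
  resolution, rebuilt at every orientation. This reads "minimum distance
  between molecule and cage" as a distance to the atomic *centres*; padding
  by per-atom radii (as the reference Open Babel implementation does) would
  be an alternative reading and is deliberately not implemented.
* **Enantiomers.** Mirroring the molecule maps the spectrophore onto the
  one computed with inversion-conjugated cages. Non-stereospecific cages
  are rotation-equivalent to their inversion image, so enantiomer
  spectrophores agree up to grid-sampling error: ≈ 0.2 % at a 5° step on
  the chiral test fixture (tested against a 2 % bound). Stereospecific
  cages are not inversion-closed and separate enantiomers clearly; the
  observed relationship between the two enantiomers' vectors is a
  permutation toward the opposite chiral cage classes, not a global sign
  flip.
* **Rotation robustness.** Re-running after an arbitrary off-grid rotation
  changes values by a few percent at a 5° step (documented 5 % bound; the
  maximum over the grid varies quadratically around interior optima but
  linearly where the optimum sits at a grid boundary) and far more at 36°
  or 60°, which is why 20° is the recommended compromise.
* **Exactness.** Translation invariance is bit-exact when the centre of
  geometry subtraction is lossless (tested on a quarter-Å lattice with 4
  atoms); in general it holds to float rounding. Positive scaling of one
  property rescales exactly that block (up to one rounding of each product).

## Synthetic fixtures: scope and limits

The fixture generator produces single atoms, diatomics, a bent triatomic, a
chiral tetrahedron, and seeded random atom clouds (6 Å box, ≥ 1 Å pairwise
separation) with synthesized neighbour lists for the hydrogen rules, plus
seeded Gaussian-jitter "conformer" families. These exercise every code path
(chirality, H-typing, charge conservation, conformer merging) but are not
chemically valid geometries: bond lengths, valences and conformational
ensembles of real drug-like molecules are not emulated. Passing tests
therefore demonstrate the correctness of the descriptor computation, not
virtual-screening performance on real libraries; the jitter families show
the qualitative within-molecule < across-molecule variability ordering, not
the magnitudes reported for real conformer ensembles.

## Known limitations

* Conformer *generation* is out of scope; the package consumes 3D
  coordinates (SDF/MOL) as given and treats every SDF record as one
  conformation, grouping conformers by identical title for merging.
* No protonation/tautomer standardization; formal charges are taken from
  the input.
* Hydrogens are expected to be explicit (the parameter table defines H
  rows); a record without them triggers a warning, not an error.
* The orientation search is a dense grid; no gradient- or
  quaternion-based refinement is attempted.
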