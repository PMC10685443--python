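# Methods

## Model overview

surfpatch treats patch analysis as three composable operations on a pair
(structure, scalar field): build a triangulated surface from the atoms,
sample the field on the surface, and segment/summarize the result.  A
fourth, independent operation integrates the field over a solvent shell
around the molecule.  Any scalar field on a regular grid can be used — the
electrostatic potential is the default, but hydration free-energy grids
(kcal·mol⁻¹·Å⁻³, e.g. from inhomogeneous solvation theory) work the same
way with adjusted isolevels.

## Surfaces

Both surface types are isosurfaces of a scalar field sampled on a regular
grid and extracted by marching cubes (scikit-image's implementation):

- **SAS**: f(x) = min_i (|x−c_i| − r_i − r_probe), 0-level, inside
  negative.  This is exact — the only error is triangulation resolution.
  For a single atom of radius 2.0 Å and a 1.4 Å probe the mesh area at
  0.4 Å spacing is within 0.5 % of the analytic 4π(3.4)² and converges as
  the spacing shrinks (the 2 % bound in the tests is deliberately loose).
- **Gaussian**: D(x) = Σ_i exp(−s(|x−c_i|²/r_i² − 1)), 1-level, inside
  positive.  With sharpness s → ∞ this tends to the union-of-spheres
  (van der Waals) envelope; the default s = 2.3 gives a moderately blended
  surface.  There is no community-standard parameterization of Gaussian
  surfaces, so absolute patch areas depend on s and the 0.5 Å default
  grid; both are flags.

The surface grid covers the structure's bounding box padded by
2·r_max + r_probe + 2·spacing, which guarantees the isosurface closes
inside the box.  Vertex areas use barycentric lumping (⅓ of incident
triangle area); they sum exactly to the total triangle area, so patch
areas partition the surface.  Vertex→atom attribution minimizes
|v − c_i| − r_i (distance to the atom *surface*, not center), so large
atoms claim the surface they generate; exact ties go to the lowest atom
serial.

## Built-in potential

The internal electrostatic model is the linearized, homogeneous-dielectric
screened Coulomb potential

φ(x) = Σ_i q_i · ℓ_B · exp(−κ|x−c_i|) / |x−c_i|    [kT/e]

with ℓ_B = e²/(4πε₀ε k_BT) (≈ 7.14 Å at ε = 78.5, T = 298.15 K) and
κ² = 8π ℓ_B N_A I·10⁻²⁷ (I in mol/L; κ⁻¹ ≈ 9.6 Å at 0.1 M).  Defaults:
298.15 K, ε = 78.5, 0.1 M 1:1 salt.  This is an approximation with known
limits: there is no low-dielectric protein interior, no dielectric
boundary polarization and no nonlinear ion response, so magnitudes near
the surface differ from a Poisson–Boltzmann solution (typically
underestimating interior-adjacent potentials).  It is exactly linear in
the charges, which the tests exploit (superposition, sign antisymmetry).
Users needing solver fidelity import an OpenDX grid computed externally;
the rest of the pipeline is agnostic to the field's origin.

Numerical guard: distances are clamped below at half the smallest grid
spacing, bounding the on-nucleus singularity without measurably changing
the potential outside the first voxel shell.

Default potential grid: bounding box + 15 Å padding at 1.0 Å spacing.  The
padding must exceed the scoring shell cutoff (10 Å); 15 Å leaves margin so
every shell voxel and every surface vertex lies strictly inside the grid.
Points outside the grid are an error, never extrapolated — silent
zero-fill would bias scores toward zero.

## Patches

Membership is vertex-based and inclusive: value ≥ iso⁺ (or ≤ iso⁻).
Components are maximal under triangle-edge adjacency, computed with
scipy's sparse connected-components; an independent breadth-first flood
fill in the test suite verifies count, membership and areas on 20 random
icosphere meshes per run.  Patches are ordered area-descending within each
sign, ties broken by lowest member vertex id, giving reproducible ranks.
Filtering applies the [min_area, max_area] window first, then keeps the
`max_patches` largest per sign.  The dominant residue of a patch maximizes
the summed lumped area of member vertices attributed to it (ties to the
lowest (chain, residue number)).  Default isolevels ±0.5 kT/e are an
analysis choice, not a physical constant; they are flags, as are all
filters.

Patch areas are vertex-lumped, not clipped at the isoline, so a patch's
area includes the full lumped area of boundary vertices; at typical
surface resolutions (0.5 Å) the difference is a band of less than one
triangle width around each patch.

## Scores

Shell selection: voxel centers that are (a) strictly outside every
probe-inflated atom sphere and (b) within `shell_cutoff` (default 10 Å) of
the nearest such sphere, measured as min_i(|x−c_i| − r_i − r_probe).
"Distance from the protein surface" is thus operationalized as distance
from the solvent-accessible surface with the same probe (1.4 Å default)
used elsewhere; voxels straddling the boundary are included or excluded
binarily by their center.  The integral is the masked voxel sum times the
voxel volume (midpoint rule), reported in kT·e⁻¹·nm³ (Å³ × 10⁻³).
`high`/`low` use strict inequalities, so voxels exactly at a cutoff count
toward `positive`/`negative` but not `high`/`low`.  Default high/low
cutoffs are ±1 kT/e and are echoed in every output.

## Synthetic fixtures and what passing tests show

The generator module provides: uniform random point charges in a box
(radius 1.5 Å, one residue per atom), single-sphere structures for the
analytic-area check, random-valued icosphere meshes (icospheres avoid the
degenerate pole triangles of UV spheres) for the segmentation oracle, and
a hard-coded 33-heavy-atom pentapeptide (Ala–Asp–Gly–Lys–Ser, zwitterionic
termini, net charge zero) for end-to-end runs.  All are deterministic per
seed.  These fixtures exercise geometry, graph segmentation, integration
and I/O exactly, but they are not proteins: they contain no packed cores,
no realistic charge distributions and no solvent structure, so passing
tests demonstrate correctness of the computation, not biophysical accuracy
of the Debye–Hückel model on real systems.  Score magnitudes on real
proteins also depend on the potential source (internal model vs. imported
solver grid) and its grid parameters.

## Numerical choices

- Trilinear interpolation with the voxel-center convention (origin =
  center of voxel 0,0,0, matching the dominant DX producer); exact on
  affine fields to machine precision; out-of-box queries raise.
- DX files are written with 6 significant digits, 3 values per line;
  round-trips are exact to printed precision.  Only diagonal delta
  matrices (axis-aligned grids) are accepted.
- PLY output is ASCII and byte-deterministic; the diverging color ramp is
  red (negative) → white (0) → blue (positive), clamped at ±5 kT/e by
  default.
- All internal lengths are Å; unit conversion to nm³ happens only at score
  reporting.
- HETATM records are kept by default (`--strip-het` removes them); only
  the first alternate location of a PDB atom is used.

## Problem sizes

Default test and acceptance runs use the 33-atom peptide (≈70 k potential
voxels, ≈4.5 k surface vertices), 31³ shell grids, and 20 icosphere meshes
of 500–2000 vertices — sizes chosen so the whole verification suite
completes in well under a minute while still exercising every code path at
meaningful resolution.

## Known limitations

- No solvent-excluded (Connolly) surface; re-entrant geometry is out of
  scope.
- The built-in potential is not a Poisson–Boltzmann solution (see above).
- No protonation/charge assignment for PDB input; charges are zero and the
  run warns that downstream scores are degenerate.
- Patch areas are resolution-dependent through the triangulation grid;
  compare areas only across runs with identical surface parameters.
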