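# surfpatch

Quantify and visualize continuous patches of a scalar potential —
electrostatics by default — on protein molecular surfaces, and compute five
volumetric electrostatics scores used as developability and recognition
descriptors for biotherapeutics.

## Who this is for

Structural bioinformaticians and antibody engineers who want to ask: where
on a protein's surface is the electrostatic potential strongly positive or
negative, how large are those patches, which residues dominate them, and
how much charged volume surrounds the molecule?  Charged surface patches
drive protease substrate preference, antigen recognition, and
chromatographic behavior of antibodies (e.g. heparin retention, which
tracks serum half-life), so compact scalar descriptors of them are useful
ranking tools.

## What it computes

Given a structure with per-atom charges and radii (PQR; plain PDB is
accepted with radii from a bundled table and zero charges) and a scalar
potential grid φ (imported as OpenDX, e.g. from APBS or GIST, or computed
internally), surfpatch:

1. **Surface** — triangulates a molecular surface by marching cubes:
   either the solvent-accessible surface, the 0-isosurface of
   f(x) = min_i(|x−c_i| − r_i − r_probe), or a Gaussian surface, the
   1-isosurface of D(x) = Σ_i exp(−s(|x−c_i|²/r_i² − 1)).
   Each vertex gets a lumped area (⅓ of its incident triangle area) and a
   nearest-atom attribution.
2. **Sampling** — interpolates φ trilinearly at every surface vertex.
3. **Patches** — finds maximal connected components of vertices with
   φ ≥ iso⁺ (positive patches) or φ ≤ iso⁻ (negative patches) in the
   triangle-edge graph, ranks them by area, reports each patch's dominant
   residue, and optionally flags patches touching marked residues (e.g.
   antibody CDRs).
4. **Scores** — selects solvent-accessible grid voxels within a cutoff
   (default 10 Å) of the probe-inflated surface and integrates φ over that
   shell: `total`, `positive` (φ>0), `negative` (φ<0), `high`
   (φ > cutoff⁺) and `low` (φ < cutoff⁻), all in kT·e⁻¹·nm³.

The built-in potential is a homogeneous-dielectric screened-Coulomb
(Debye–Hückel) model, φ(x) = Σ_i q_i ℓ_B e^{−κ|x−c_i|}/|x−c_i| in kT/e,
with ℓ_B the Bjerrum length and κ the inverse Debye length (0.1 M 1:1 salt
by default).  It keeps the pipeline self-contained; for Poisson–Boltzmann
fidelity import an APBS grid via `--potential`.

## Worked example

The package bundles a synthetic neutral pentapeptide (Ala–Asp–Gly–Lys–Ser,
33 heavy atoms, Asp⁻/Lys⁺) so everything runs offline:

```sh
surfpatch fixtures --kind peptide --out peptide.pqr
surfpatch run --in peptide.pqr --out-dir out/
```

With the default SAS surface (0.5 Å grid, 1.4 Å probe), internal potential
(1.0 Å grid, 0.1 M salt) and ±0.5 kT/e isolevels this prints

```
run complete: 4 patches, total score -0.084 kT/e nm^3 -> out
```

and writes `out/patches.csv`:

| sign | rank | area_A2 | top residue |
|------|------|---------|-------------|
| +    | 1    | 122.6   | ALA 1       |
| +    | 2    | 107.1   | LYS 4       |
| −    | 1    | 204.3   | SER 5       |
| −    | 2    | 94.2    | ASP 2       |

The positive patches sit over the protonated N-terminus and the lysine
ammonium; the negative ones over the C-terminal carboxylate and the
aspartate.  `out/scores.json` reports the five shell integrals
(total −0.084, positive +1.608, negative −1.692, high +0.084,
low −0.031 kT·e⁻¹·nm³ over 23 045 shell voxels): the peptide is net
neutral, so `total` is near zero while `positive` and `negative` balance.
`out/surface_value.ply` (red = negative, white = 0, blue = positive,
clamped at ±5 kT/e) and `out/surface_patch.ply` can be opened in any mesh
viewer, and `out/bundle.npz` holds every per-vertex array plus parameter
metadata.

Other subcommands: `surfpatch potential` (write the internal potential as
DX), `surfpatch surface`, `surfpatch scores`, `surfpatch fixtures`.
Parameters may be given in a TOML file (`--config`); explicit flags win.

## Scope notes

- Solvent-excluded (Connolly) surfaces are not implemented.
- No Poisson–Boltzmann solving, protonation assignment, or antibody
  numbering: prepare inputs with PDB2PQR/APBS and pass CDR ranges as
  `--mark-residues H:26-32,...` if needed.
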