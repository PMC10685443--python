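"""Synthetic fixtures: point-charge structures, spheres, labeled meshes and
a toy peptide.

Everything here is generated in memory and bit-reproducible per seed, so the
whole pipeline can be exercised without downloading structures or running an
external electrostatics solver.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .structures import Atom, Structure, parse_pqr
from .surface import SurfaceMesh, _lumped_vertex_areas

__all__ = [
    "FixtureSpec",
    "make_point_charges",
    "make_sphere_structure",
    "make_labeled_mesh",
    "toy_peptide",
    "TOY_PEPTIDE_PQR",
]


# Extended-chain pentapeptide Ala–Asp–Gly–Lys–Ser, heavy atoms only, with
# idealized backbone geometry.  Hydrogen charges are collapsed onto their
# heavy atoms; each residue sums to its formal charge (zwitterionic termini,
# Asp −1, Lys +1) so the peptide is net neutral with both strongly positive
# (Lys NZ) and strongly negative (Asp carboxylate, C-terminus) regions.
# Synthetic — not derived from any deposited structure.
TOY_PEPTIDE_PQR = """\
ATOM 1 N ALA A 1 0.000 0.000 0.000 0.6000 1.5500
ATOM 2 CA ALA A 1 1.200 0.900 0.000 0.2500 1.7000
ATOM 3 C ALA A 1 2.400 0.000 0.000 0.6000 1.7000
ATOM 4 O ALA A 1 2.400 -1.230 0.000 -0.5700 1.5200
ATOM 5 CB ALA A 1 1.350 0.900 1.500 0.1200 1.7000
ATOM 6 N ASP A 2 3.600 0.000 0.000 -0.4200 1.5500
ATOM 7 CA ASP A 2 4.800 -0.900 0.000 0.0300 1.7000
ATOM 8 C ASP A 2 6.000 0.000 0.000 0.6000 1.7000
ATOM 9 O ASP A 2 6.000 1.230 0.000 -0.5700 1.5200
ATOM 10 CB ASP A 2 4.950 -0.900 -1.500 0.2600 1.7000
ATOM 11 CG ASP A 2 5.100 -0.900 -3.000 0.6600 1.7000
ATOM 12 OD1 ASP A 2 5.250 -0.900 -4.500 -0.7800 1.5200
ATOM 13 OD2 ASP A 2 5.400 -0.900 -6.000 -0.7800 1.5200
ATOM 14 N GLY A 3 7.200 0.000 0.000 -0.4200 1.5500
ATOM 15 CA GLY A 3 8.400 0.900 0.000 0.3900 1.7000
ATOM 16 C GLY A 3 9.600 0.000 0.000 0.6000 1.7000
ATOM 17 O GLY A 3 9.600 -1.230 0.000 -0.5700 1.5200
ATOM 18 N LYS A 4 10.800 0.000 0.000 -0.4200 1.5500
ATOM 19 CA LYS A 4 12.000 -0.900 0.000 0.0300 1.7000
ATOM 20 C LYS A 4 13.200 0.000 0.000 0.6000 1.7000
ATOM 21 O LYS A 4 13.200 1.230 0.000 -0.5700 1.5200
ATOM 22 CB LYS A 4 12.150 -0.900 -1.500 0.2300 1.7000
ATOM 23 CG LYS A 4 12.300 -0.900 -3.000 0.0000 1.7000
ATOM 24 CD LYS A 4 12.450 -0.900 -4.500 0.0000 1.7000
ATOM 25 CE LYS A 4 12.600 -0.900 -6.000 0.2000 1.7000
ATOM 26 NZ LYS A 4 12.750 -0.900 -7.500 0.9300 1.5500
ATOM 27 N SER A 5 14.400 0.000 0.000 -0.4200 1.5500
ATOM 28 CA SER A 5 15.600 0.900 0.000 0.2000 1.7000
ATOM 29 C SER A 5 16.800 0.000 0.000 0.7500 1.7000
ATOM 30 O SER A 5 16.800 -1.230 0.000 -0.8000 1.5200
ATOM 31 CB SER A 5 15.750 0.900 1.500 0.3000 1.7000
ATOM 32 OG SER A 5 15.900 0.900 3.000 -0.2300 1.5200
ATOM 33 OXT SER A 5 17.400 1.100 0.000 -0.8000 1.5200
"""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for the random point-charge generator."""

    seed: int = 0
    n_atoms: int = 10
    box: float = 10.0                       # cubic box edge, Å
    charge_range: tuple[float, float] = (-1.0, 1.0)  # e


def make_point_charges(spec: FixtureSpec) -> Structure:
    """Random point charges in a cubic box: uniform positions, uniform
    charges, radius 1.5 Å, one residue per atom.  Deterministic per seed."""
    if spec.n_atoms < 1:
        raise ValueError("n_atoms must be ≥ 1")
    rng = np.random.default_rng(spec.seed)
    positions = rng.uniform(0.0, spec.box, size=(spec.n_atoms, 3))
    lo, hi = spec.charge_range
    charges = rng.uniform(lo, hi, size=spec.n_atoms)
    atoms = [
        Atom(
            serial=i + 1,
            name="Q",
            residue_name="CHG",
            chain_id="A",
            residue_number=i + 1,
            position=positions[i],
            charge=float(charges[i]),
            radius=1.5,
        )
        for i in range(spec.n_atoms)
    ]
    return Structure(atoms=atoms, title=f"point charges seed={spec.seed}")


def make_sphere_structure(radius: float) -> Structure:
    """A single neutral atom at the origin — the analytic sphere fixture
    whose SAS is exactly a sphere of radius r + probe."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return Structure(
        atoms=[
            Atom(
                serial=1, name="X", residue_name="SPH", chain_id="A",
                residue_number=1, position=np.zeros(3), charge=0.0,
                radius=float(radius),
            )
        ],
        title=f"sphere r={radius}",
    )


def _icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere by repeated edge-midpoint subdivision of an
    icosahedron.  No degenerate pole triangles, unlike a UV sphere."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        vlist = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in midpoint:
                m = vlist[a] + vlist[b]
                m /= np.linalg.norm(m)
                midpoint[key] = len(vlist)
                vlist.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces)
    return verts, faces


def make_labeled_mesh(seed: int, n_vertices: int = 500) -> SurfaceMesh:
    """An icosphere mesh with at least ``n_vertices`` vertices and i.i.d.
    uniform vertex values in [−2, 2].  Deterministic per seed."""
    if n_vertices < 12:
        raise ValueError("n_vertices must be ≥ 12")
    subdivisions = 0
    while 10 * 4**subdivisions + 2 < n_vertices:
        subdivisions += 1
    verts, faces = _icosphere(subdivisions)
    rng = np.random.default_rng(seed)
    mesh = SurfaceMesh(
        vertices=verts * 10.0,  # 10 Å sphere, protein-ish scale
        triangles=faces,
        vertex_area=_lumped_vertex_areas(verts * 10.0, faces),
    )
    mesh.vertex_value = rng.uniform(-2.0, 2.0, size=len(verts))
    mesh.value_unit = "kT/e"
    return mesh


def toy_peptide() -> Structure:
    """The bundled pentapeptide as a parsed Structure."""
    return parse_pqr(io.StringIO(TOY_PEPTIDE_PQR), title="toy pentapeptide")
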