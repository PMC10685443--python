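"""Built-in screened-Coulomb (Debye–Hückel) potential grids.

This module provides a self-contained electrostatic potential so the patch
pipeline runs without an external Poisson–Boltzmann solver.  The model is a
homogeneous-dielectric linearized approximation:

    φ(x) = Σ_i q_i · ℓ_B · exp(−κ |x − c_i|) / |x − c_i|      [kT/e]

with the Bjerrum length ℓ_B = e² / (4π ε₀ ε k_B T) and the inverse Debye
length κ² = 8π ℓ_B N_A I · 10⁻²⁷ (I the 1:1 ionic strength in mol/L, all
lengths in Å).  There is no low-dielectric protein cavity: potentials near
and inside the molecule are less accurate than a Poisson–Boltzmann solution.
For solver-grade fidelity, import an externally computed grid in OpenDX
format instead (e.g. from APBS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .grid import GridSpec, ScalarGrid
from .structures import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "SolventModel",
    "bjerrum_length",
    "inverse_debye_length",
    "debye_huckel_grid",
    "default_grid_spec",
]


@dataclass(frozen=True)
class SolventModel:
    """Solvent parameters for the screened-Coulomb potential.

    Defaults are aqueous 0.1 M NaCl at room temperature; the output unit is
    fixed to kT/e (thermal energy per elementary charge).
    """

    temperature: float = 298.15       # K
    solvent_dielectric: float = 78.5  # relative permittivity
    ionic_strength: float = 0.1       # mol/L, 1:1 electrolyte
    unit: str = "kT/e"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.solvent_dielectric < 1:
            raise ValueError("dielectric must be ≥ 1")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be ≥ 0")


def bjerrum_length(model: SolventModel) -> float:
    """Bjerrum length ℓ_B = e²/(4π ε₀ ε k_B T) in Å (~7.1 Å in water, 298 K)."""
    lb_m = constants.e**2 / (
        4.0 * np.pi * constants.epsilon_0 * model.solvent_dielectric
        * constants.k * model.temperature
    )
    return lb_m * 1e10


def inverse_debye_length(model: SolventModel) -> float:
    """Inverse Debye screening length κ in Å⁻¹.

    κ² = 8π ℓ_B n with n = N_A · I · 10⁻²⁷ the per-species number density
    of a 1:1 electrolyte in Å⁻³.
    """
    lb = bjerrum_length(model)
    n_density = constants.N_A * model.ionic_strength * 1e-27
    return float(np.sqrt(8.0 * np.pi * lb * n_density))


def debye_huckel_grid(
    structure: Structure,
    spec: GridSpec,
    model: SolventModel | None = None,
) -> ScalarGrid:
    """Evaluate the screened-Coulomb potential of the structure's point
    charges on a grid, in kT/e.

    Distances are clamped below at half the smallest grid spacing so the
    potential stays bounded at voxels that coincide with a nucleus; the
    clamp does not materially change the exterior potential.
    """
    model = model or SolventModel()
    charges = structure.charges
    if len(structure) == 0 or np.all(charges == 0):
        logger.warning("structure carries no net charges; potential grid is zero")
        return ScalarGrid(spec, np.zeros(spec.shape), unit=model.unit)
    centers = structure.positions
    lo, hi = spec.origin, spec.upper
    if np.all(np.any((centers < lo) | (centers > hi), axis=1)):
        logger.warning("all atoms lie outside the grid box %s..%s", lo, hi)
    lb = bjerrum_length(model)
    kappa = inverse_debye_length(model)
    r_min = 0.5 * float(spec.spacing.min())
    points = spec.voxel_centers()
    phi = np.zeros(len(points))
    # Chunk over atoms to keep the (n_voxels × n_atoms) distance matrix small.
    chunk = max(1, int(2e7) // max(len(points), 1))
    for start in range(0, len(centers), chunk):
        c = centers[start : start + chunk]
        q = charges[start : start + chunk]
        d = np.linalg.norm(points[:, None, :] - c[None, :, :], axis=2)
        np.maximum(d, r_min, out=d)
        phi += (q[None, :] * lb * np.exp(-kappa * d) / d).sum(axis=1)
    return ScalarGrid(spec, phi.reshape(spec.shape), unit=model.unit)


def default_grid_spec(
    structure: Structure, spacing: float = 1.0, padding: float = 15.0
) -> GridSpec:
    """Grid covering the structure's bounding box plus ``padding`` Å on every
    side.  The default 15 Å pad leaves room for the 10 Å scoring shell."""
    pos = structure.positions
    lo = pos.min(axis=0) - padding
    hi = pos.max(axis=0) + padding
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return GridSpec(origin=lo, spacing=np.full(3, spacing), shape=shape)
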