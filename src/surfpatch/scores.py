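"""Volumetric electrostatics scores over a solvent-accessible shell.

Five descriptors summarize the potential in the solvent region within a
distance cutoff (default 10 Å) of the probe-inflated molecular surface:

* ``total``    — integral of φ over the shell,
* ``positive`` — integral over shell voxels with φ > 0,
* ``negative`` — integral over shell voxels with φ < 0,
* ``high``     — integral over shell voxels with φ > high_cutoff,
* ``low``      — integral over shell voxels with φ < low_cutoff.

The integral is approximated as the voxel sum times the voxel volume
(midpoint rule).  Grid values are in kT/e and spacings in Å; scores are
reported in kT·e⁻¹·nm³ (1 Å³ = 10⁻³ nm³).  Intuitively, ``total`` is the
interaction strength with a unit positive charge smeared uniformly over the
shell; ``positive``/``negative`` restrict that charge to the same-sign
region, and ``high``/``low`` to the strongly charged regions only.
Positively charged binders (e.g. heparin-retained antibodies) track the
``positive`` and ``high`` descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .grid import ScalarGrid, ShellMask

logger = logging.getLogger(__name__)

__all__ = ["ScoreParams", "ScoreSet", "integrate_scores"]

A3_TO_NM3 = 1e-3


@dataclass(frozen=True)
class ScoreParams:
    """Shell geometry and the high/low potential cutoffs (grid units)."""

    shell_cutoff: float = 10.0   # Å
    probe_radius: float = 1.4    # Å
    high_cutoff: float = 1.0     # grid units, > 0
    low_cutoff: float = -1.0     # grid units, < 0

    def __post_init__(self) -> None:
        if self.shell_cutoff <= 0:
            raise ValueError("shell_cutoff must be > 0")
        if not (self.high_cutoff > 0 > self.low_cutoff):
            raise ValueError("need high_cutoff > 0 > low_cutoff")


@dataclass(frozen=True)
class ScoreSet:
    """The five volumetric scores in kT·e⁻¹·nm³, plus shell bookkeeping."""

    total: float
    positive: float
    negative: float
    high: float
    low: float
    voxel_volume: float  # nm³
    n_voxels: int
    unit: str = "kT/e nm^3"

    def to_dict(self) -> dict:
        return asdict(self)


def integrate_scores(
    grid: ScalarGrid, mask: ShellMask, params: ScoreParams | None = None
) -> ScoreSet:
    """Integrate the potential over the masked shell.

    ``high``/``low`` use strict inequalities against their cutoffs, so
    boundary voxels are excluded.  An empty mask yields an all-zero score
    set with a warning.
    """
    params = params or ScoreParams()
    if mask.mask.shape != grid.values.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} != grid shape {grid.values.shape}"
        )
    v_nm3 = grid.spec.voxel_volume_A3 * A3_TO_NM3
    phi = grid.values[mask.mask]
    if phi.size == 0:
        logger.warning("empty shell mask; all scores are zero")
        return ScoreSet(0.0, 0.0, 0.0, 0.0, 0.0, v_nm3, 0)
    return ScoreSet(
        total=float(v_nm3 * phi.sum()),
        positive=float(v_nm3 * phi[phi > 0].sum()),
        negative=float(v_nm3 * phi[phi < 0].sum()),
        high=float(v_nm3 * phi[phi > params.high_cutoff].sum()),
        low=float(v_nm3 * phi[phi < params.low_cutoff].sum()),
        voxel_volume=v_nm3,
        n_voxels=int(phi.size),
    )
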