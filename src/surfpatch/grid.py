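"""Regular scalar grids: OpenDX I/O, trilinear sampling, solvent shells.

Coordinate convention follows APBS: the grid origin is the *center* of voxel
(0, 0, 0), and voxel centers are at ``origin + index * spacing``.  Only
axis-aligned (diagonal-delta) grids are supported.

The OpenDX grammar accepted here is the APBS dialect::

    object 1 class gridpositions counts nx ny nz
    origin ox oy oz
    delta dx 0 0
    delta 0 dy 0
    delta 0 0 dz
    object 2 class gridconnections counts nx ny nz
    object 3 class array type double rank 0 items N data follows
    <N values, whitespace separated, C order (z fastest)>

Comment lines start with ``#``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .structures import EmptyStructureError, Structure

__all__ = [
    "GridSpec",
    "ScalarGrid",
    "ShellMask",
    "DXFormatError",
    "OutOfBoundsError",
    "read_dx",
    "write_dx",
    "trilinear_interpolate",
    "shell_mask",
]


class DXFormatError(ValueError):
    """The DX stream is malformed or uses an unsupported grid geometry."""


class OutOfBoundsError(ValueError):
    """A query point lies outside the grid bounding box."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: origin (Å, center of voxel 0,0,0),
    per-axis spacing (Å) and shape."""

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float)
        shape = tuple(int(n) for n in self.shape)
        if origin.shape != (3,) or spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if np.any(spacing <= 0):
            raise ValueError(f"spacing must be positive, got {spacing}")
        if len(shape) != 3 or any(n < 2 for n in shape):
            raise ValueError(f"shape must be ≥2 on each axis, got {shape}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    @property
    def upper(self) -> np.ndarray:
        """Center of the last voxel (Å)."""
        return self.origin + (np.array(self.shape) - 1) * self.spacing

    @property
    def voxel_volume_A3(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates."""
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """(nx*ny*nz, 3) array of voxel-center coordinates, C order."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)


@dataclass
class ScalarGrid:
    """A scalar field sampled on a regular grid, with a unit tag."""

    spec: GridSpec
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {values.shape} != grid shape {self.spec.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("grid contains non-finite values")
        self.values = values


@dataclass
class ShellMask:
    """Boolean voxel selection: solvent-accessible and within a distance
    cutoff of the probe-inflated atom surface."""

    mask: np.ndarray
    probe_radius: float
    shell_cutoff: float

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def read_dx(stream: IO[str] | Iterable[str], *, unit: str = "") -> ScalarGrid:
    """Read an APBS-dialect OpenDX scalar grid.

    The unit tag is not stored in DX files; pass it via ``unit``.
    """
    shape: tuple[int, int, int] | None = None
    origin: np.ndarray | None = None
    deltas: list[np.ndarray] = []
    data: list[float] = []
    n_expected: int | None = None
    in_data = False
    for line in stream:
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if in_data:
            tokens = stripped.split()
            if tokens[0] in ("attribute", "component", "object", "end"):
                in_data = False
                continue
            data.extend(float(t) for t in tokens)
            continue
        tokens = stripped.split()
        if tokens[0] == "object" and "gridpositions" in tokens:
            shape = (int(tokens[-3]), int(tokens[-2]), int(tokens[-1]))
        elif tokens[0] == "origin":
            origin = np.array([float(t) for t in tokens[1:4]])
        elif tokens[0] == "delta":
            deltas.append(np.array([float(t) for t in tokens[1:4]]))
        elif tokens[0] == "object" and "data" in tokens and "follows" in tokens:
            idx = tokens.index("items")
            n_expected = int(tokens[idx + 1])
            in_data = True
    if shape is None or origin is None or len(deltas) != 3:
        raise DXFormatError("incomplete DX header (counts, origin or deltas missing)")
    delta_matrix = np.array(deltas)
    if not np.allclose(delta_matrix, np.diag(np.diag(delta_matrix))):
        raise DXFormatError(
            f"unsupported grid: delta vectors are not axis-aligned:\n{delta_matrix}"
        )
    spacing = np.diag(delta_matrix)
    n_total = int(np.prod(shape))
    if n_expected is not None and n_expected != n_total:
        raise DXFormatError(
            f"declared item count {n_expected} != shape product {n_total}"
        )
    if len(data) != n_total:
        raise DXFormatError(
            f"truncated DX file: expected {n_total} values, got {len(data)}"
        )
    values = np.array(data).reshape(shape)
    return ScalarGrid(GridSpec(origin, spacing, shape), values, unit=unit)


def write_dx(grid: ScalarGrid, stream: IO[str], *, comment: str = "") -> None:
    """Write an APBS-readable OpenDX file, three values per data line.

    Output is deterministic for identical input.  Grids with non-finite
    values are refused.
    """
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("refusing to write grid with non-finite values")
    nx, ny, nz = grid.spec.shape
    ox, oy, oz = grid.spec.origin
    dx, dy, dz = grid.spec.spacing
    if comment:
        for line in comment.splitlines():
            stream.write(f"# {line}\n")
    stream.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    stream.write(f"origin {ox:.6e} {oy:.6e} {oz:.6e}\n")
    stream.write(f"delta {dx:.6e} 0.000000e+00 0.000000e+00\n")
    stream.write(f"delta 0.000000e+00 {dy:.6e} 0.000000e+00\n")
    stream.write(f"delta 0.000000e+00 0.000000e+00 {dz:.6e}\n")
    stream.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    n = nx * ny * nz
    stream.write(
        f"object 3 class array type double rank 0 items {n} data follows\n"
    )
    flat = grid.values.ravel(order="C")
    for i in range(0, n, 3):
        chunk = flat[i : i + 3]
        stream.write(" ".join(f"{v:.6e}" for v in chunk) + "\n")
    stream.write('attribute "dep" string "positions"\n')
    stream.write('object "regular positions regular connections" class field\n')


def trilinear_interpolate(grid: ScalarGrid, points: Sequence | np.ndarray) -> np.ndarray:
    """Trilinearly interpolate the grid at the given points (Å).

    Exact at voxel centers and on affine fields.  Points outside the grid
    bounding box (voxel-center convention) raise :class:`OutOfBoundsError`;
    there is no extrapolation.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = grid.spec.origin, grid.spec.upper
    eps = 1e-9 * np.maximum(np.abs(hi - lo), 1.0)
    outside = np.any((points < lo - eps) | (points > hi + eps), axis=1)
    if np.any(outside):
        bad = points[np.argmax(outside)]
        raise OutOfBoundsError(
            f"point {bad} lies outside grid box [{lo}, {hi}]; "
            "enlarge the grid padding"
        )
    interp = RegularGridInterpolator(
        grid.spec.axes(), grid.values, method="linear",
        bounds_error=False, fill_value=None,
    )
    # fill_value=None allows the eps-tolerant boundary points through; true
    # outsiders were already rejected above.
    return np.asarray(interp(points), dtype=float)


def _min_surface_distance(
    points: np.ndarray, structure: Structure, probe_radius: float,
    chunk: int = 256,
) -> np.ndarray:
    """min over atoms of (|x - c_i| - r_i - probe) for each point (Å)."""
    centers = structure.positions
    radii = structure.radii
    best = np.full(len(points), np.inf)
    for start in range(0, len(centers), chunk):
        c = centers[start : start + chunk]
        r = radii[start : start + chunk]
        d = np.linalg.norm(points[:, None, :] - c[None, :, :], axis=2)
        np.minimum(best, (d - r[None, :] - probe_radius).min(axis=1), out=best)
    return best


def shell_mask(
    grid_spec: GridSpec,
    structure: Structure,
    probe_radius: float = 1.4,
    shell_cutoff: float = 10.0,
) -> ShellMask:
    """Select solvent-accessible voxels within ``shell_cutoff`` Å of the
    probe-inflated atom surface.

    A voxel center x is selected iff it is outside every probe-inflated
    atom sphere (solvent accessible) and its signed distance to the nearest
    such sphere is ≤ ``shell_cutoff``.  Inclusion is binary by voxel center.
    """
    if len(structure) == 0:
        raise EmptyStructureError("cannot build a solvent shell around no atoms")
    if probe_radius < 0:
        raise ValueError("probe_radius must be ≥ 0")
    if shell_cutoff <= 0:
        raise ValueError("shell_cutoff must be > 0")
    centers = grid_spec.voxel_centers()
    dist = _min_surface_distance(centers, structure, probe_radius)
    mask = (dist > 0) & (dist <= shell_cutoff)
    return ShellMask(
        mask=mask.reshape(grid_spec.shape),
        probe_radius=probe_radius,
        shell_cutoff=shell_cutoff,
    )
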