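"""Visualization and archive exports.

PLY surfaces carry per-vertex uint8 RGB colors.  Value mode maps the sampled
potential onto a red–white–blue diverging ramp (red = most negative, white =
zero, blue = most positive), clamped at ±``clamp``.  Patch mode colors each
patch distinctly, shading by area rank within its sign, with unpatched
vertices grey.  ASCII PLY is written by default so outputs diff cleanly.

The bundle archive is an npz file holding every per-vertex array plus a JSON
metadata block (parameters, units, scores), sufficient to reconstruct the
annotated surface without rerunning the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, BinaryIO, Sequence

import numpy as np

from .patches import Patch, patch_vertex_labels
from .scores import ScoreSet
from .surface import SurfaceMesh

__all__ = ["ColorMap", "write_ply", "write_bundle", "read_bundle"]

_RED = np.array([255, 0, 0])
_WHITE = np.array([255, 255, 255])
_BLUE = np.array([0, 0, 255])
_GREY = np.array([128, 128, 128])


@dataclass(frozen=True)
class ColorMap:
    """Coloring scheme: by sampled value (diverging) or by patch identity."""

    mode: str = "value"   # "value" | "patch"
    clamp: float = 5.0    # grid units; ±clamp maps to the pure anchors

    def __post_init__(self) -> None:
        if self.mode not in ("value", "patch"):
            raise ValueError(f"unknown colormap mode {self.mode!r}")
        if self.clamp <= 0:
            raise ValueError("clamp must be positive")


def _value_colors(values: np.ndarray, clamp: float) -> np.ndarray:
    t = np.clip(values / clamp, -1.0, 1.0)
    colors = np.empty((len(t), 3))
    neg = t < 0
    # white at 0, pure red at -1, pure blue at +1
    colors[neg] = _WHITE + (-t[neg, None]) * (_RED - _WHITE)
    colors[~neg] = _WHITE + (t[~neg, None]) * (_BLUE - _WHITE)
    return np.rint(colors).astype(np.uint8)


def _patch_colors(labels: np.ndarray, patches: Sequence[Patch]) -> np.ndarray:
    colors = np.tile(_GREY, (len(labels), 1)).astype(np.uint8)
    n_per_sign = {
        s: max(sum(1 for p in patches if p.sign == s), 1) for s in ("+", "-")
    }
    for i, p in enumerate(patches):
        # rank 1 saturated, later ranks progressively whiter
        frac = (p.rank - 1) / max(n_per_sign[p.sign], 2)
        anchor = _BLUE if p.sign == "+" else _RED
        rgb = np.rint(anchor + frac * (_WHITE - anchor)).astype(np.uint8)
        colors[labels == i] = rgb
    return colors


def write_ply(
    mesh: SurfaceMesh,
    stream: IO[str],
    colormap: ColorMap | None = None,
    patches: Sequence[Patch] | None = None,
) -> None:
    """Write the mesh as ASCII PLY with per-vertex RGB.

    Deterministic byte-for-byte for identical inputs.
    """
    colormap = colormap or ColorMap()
    if colormap.mode == "value":
        if mesh.vertex_value is None:
            raise ValueError("value-mode PLY needs sampled vertex values")
        colors = _value_colors(mesh.vertex_value, colormap.clamp)
    else:
        if patches is None:
            raise ValueError("patch-mode PLY needs the patch list")
        labels = patch_vertex_labels(patches, mesh.n_vertices)
        colors = _patch_colors(labels, patches)
    stream.write("ply\n")
    stream.write("format ascii 1.0\n")
    stream.write(f"element vertex {mesh.n_vertices}\n")
    for prop in ("x", "y", "z"):
        stream.write(f"property float {prop}\n")
    for prop in ("red", "green", "blue"):
        stream.write(f"property uchar {prop}\n")
    stream.write(f"element face {mesh.n_triangles}\n")
    stream.write("property list uchar int vertex_indices\n")
    stream.write("end_header\n")
    for v, c in zip(mesh.vertices, colors):
        stream.write(
            f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {c[0]} {c[1]} {c[2]}\n"
        )
    for tri in mesh.triangles:
        stream.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def write_bundle(
    mesh: SurfaceMesh,
    patches: Sequence[Patch],
    scores: ScoreSet | None,
    stream: BinaryIO | str,
    parameters: dict | None = None,
) -> None:
    """Archive the annotated surface: all per-vertex arrays, the patch id
    labeling, and a JSON metadata block with parameters and scores."""
    metadata = {
        "parameters": parameters or {},
        "value_unit": mesh.value_unit,
        "scores": scores.to_dict() if scores is not None else None,
    }
    arrays = {
        "vertices": mesh.vertices,
        "triangles": mesh.triangles,
        "vertex_area": mesh.vertex_area,
        "patch_id": patch_vertex_labels(patches, mesh.n_vertices),
        "metadata_json": np.array(json.dumps(metadata, sort_keys=True)),
    }
    if mesh.vertex_value is not None:
        arrays["vertex_value"] = mesh.vertex_value
    if mesh.nearest_atom is not None:
        arrays["nearest_atom"] = mesh.nearest_atom
    np.savez(stream, **arrays)


def read_bundle(stream: BinaryIO | str) -> tuple[SurfaceMesh, np.ndarray, dict]:
    """Read a bundle back: (mesh, per-vertex patch ids, metadata dict)."""
    with np.load(stream, allow_pickle=False) as data:
        metadata = json.loads(str(data["metadata_json"]))
        mesh = SurfaceMesh(
            vertices=data["vertices"],
            triangles=data["triangles"],
            vertex_area=data["vertex_area"],
            vertex_value=data["vertex_value"] if "vertex_value" in data else None,
            value_unit=metadata.get("value_unit", ""),
            nearest_atom=data["nearest_atom"] if "nearest_atom" in data else None,
        )
        return mesh, data["patch_id"], metadata
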