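"""Connected-component patch segmentation on value-annotated meshes.

A positive patch is a maximal set of mesh vertices, connected through
triangle edges, whose sampled value is ≥ the positive isolevel; a negative
patch is the analogue with value ≤ the negative isolevel.  Threshold
comparisons are inclusive.  Patch area is the sum of the member vertices'
lumped areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .structures import Structure
from .surface import SurfaceMesh

__all__ = [
    "PatchParams",
    "Patch",
    "segment_patches",
    "filter_patches",
    "summarize_patches",
    "patch_vertex_labels",
]


@dataclass(frozen=True)
class PatchParams:
    """Isolevels and filters for patch detection.

    Default isolevels of ±0.5 kT/e suit electrostatic potentials; adjust for
    other fields (e.g. hydration free-energy grids in kcal/mol/Å³).
    """

    positive_isovalue: float = 0.5
    negative_isovalue: float = -0.5
    min_area: float = 0.0          # Å²
    max_area: float = np.inf       # Å²
    max_patches: int | None = None  # per sign

    def __post_init__(self) -> None:
        if self.positive_isovalue <= self.negative_isovalue:
            raise ValueError("positive isolevel must exceed the negative one")
        if self.min_area < 0:
            raise ValueError("min_area must be ≥ 0")


@dataclass
class Patch:
    """A sign-labeled connected vertex set with its lumped area."""

    sign: str                      # "+" or "-"
    vertex_ids: np.ndarray         # sorted member vertex indices
    area: float                    # Å²
    rank: int = 0                  # 1 = largest of its sign
    top_residue: tuple[str, int, str] | None = None  # (chain, number, name)
    contains_marked_residue: bool = False

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)


def _components(vertex_mask: np.ndarray, edges: np.ndarray, n: int) -> list[np.ndarray]:
    """Connected components of the subgraph induced by ``vertex_mask``."""
    idx = np.flatnonzero(vertex_mask)
    if len(idx) == 0:
        return []
    remap = -np.ones(n, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    keep = vertex_mask[edges[:, 0]] & vertex_mask[edges[:, 1]]
    e = remap[edges[keep]]
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(idx), len(idx))
    )
    n_comp, labels = connected_components(adj, directed=False)
    return [idx[labels == k] for k in range(n_comp)]


def segment_patches(mesh: SurfaceMesh, params: PatchParams) -> list[Patch]:
    """Find all positive and negative patches on the mesh.

    Patches are ordered area-descending within each sign (ties broken by the
    lowest member vertex id) and ranked from 1.  An empty result is valid.
    """
    if mesh.vertex_value is None:
        raise ValueError("mesh has no sampled values; run sample_on_mesh first")
    values = mesh.vertex_value
    edges = mesh.edges()
    n = mesh.n_vertices
    out: list[Patch] = []
    for sign, mask in (
        ("+", values >= params.positive_isovalue),
        ("-", values <= params.negative_isovalue),
    ):
        patches = [
            Patch(sign=sign, vertex_ids=np.sort(comp),
                  area=float(mesh.vertex_area[comp].sum()))
            for comp in _components(mask, edges, n)
        ]
        patches.sort(key=lambda p: (-p.area, int(p.vertex_ids[0])))
        for rank, p in enumerate(patches, start=1):
            p.rank = rank
        out.extend(patches)
    return out


def filter_patches(patches: Sequence[Patch], params: PatchParams) -> list[Patch]:
    """Apply the area window, then keep the ``max_patches`` largest per sign.

    Ranks are recomputed; the area-descending order within each sign is
    preserved.
    """
    out: list[Patch] = []
    for sign in ("+", "-"):
        kept = [
            p for p in patches
            if p.sign == sign and params.min_area <= p.area <= params.max_area
        ]
        kept.sort(key=lambda p: (-p.area, int(p.vertex_ids[0])))
        if params.max_patches is not None:
            kept = kept[: params.max_patches]
        for rank, p in enumerate(kept, start=1):
            p.rank = rank
        out.extend(kept)
    return out


def summarize_patches(
    patches: Sequence[Patch],
    mesh: SurfaceMesh,
    structure: Structure,
    marked_residues: set[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Tabulate patches: sign, rank, area, vertex count, dominant residue
    and whether the patch touches any marked residue.

    The dominant residue is the one whose attributed vertices contribute the
    most lumped area to the patch (ties broken by lowest (chain, number)).
    ``marked_residues`` is a set of (chain_id, residue_number) pairs — e.g.
    antibody CDR ranges supplied by the user.
    """
    if mesh.nearest_atom is None:
        raise ValueError(
            "mesh has no atom attribution; run attribute_vertices first"
        )
    marked_residues = marked_residues or set()
    rows = []
    for p in patches:
        atoms = mesh.nearest_atom[p.vertex_ids]
        areas = mesh.vertex_area[p.vertex_ids]
        by_residue: dict[tuple[str, int, str], float] = {}
        touches_marked = False
        for atom_idx, va in zip(atoms, areas):
            a = structure[int(atom_idx)]
            key = (a.chain_id, a.residue_number, a.residue_name)
            by_residue[key] = by_residue.get(key, 0.0) + va
            if (a.chain_id, a.residue_number) in marked_residues:
                touches_marked = True
        top = min(by_residue.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))[0]
        p.top_residue = top
        p.contains_marked_residue = touches_marked
        rows.append(
            {
                "sign": p.sign,
                "rank": p.rank,
                "area_A2": p.area,
                "n_vertices": p.n_vertices,
                "top_residue_chain": top[0],
                "top_residue_number": top[1],
                "top_residue_name": top[2],
                "contains_marked_residue": touches_marked,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sign", "rank", "area_A2", "n_vertices", "top_residue_chain",
            "top_residue_number", "top_residue_name", "contains_marked_residue",
        ],
    )


def patch_vertex_labels(patches: Sequence[Patch], n_vertices: int) -> np.ndarray:
    """Per-vertex patch id: -1 for unpatched vertices, otherwise the index of
    the patch in ``patches``."""
    labels = np.full(n_vertices, -1, dtype=np.int64)
    for i, p in enumerate(patches):
        labels[p.vertex_ids] = i
    return labels
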