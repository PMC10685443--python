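import numpy as np
import pytest

from surfpatch.patches import (
    PatchParams,
    filter_patches,
    patch_vertex_labels,
    segment_patches,
    summarize_patches,
)
from surfpatch.structures import Atom, Structure
from surfpatch.surface import SurfaceMesh
from surfpatch.synthetic import make_labeled_mesh

from conftest import flood_fill_components, mesh_adjacency


def assert_patch_invariants(patches, mesh, params):
    """The structural contract of a patch list: membership thresholds,
    connectivity maximality, disjointness within each sign."""
    adj = mesh_adjacency(mesh.triangles, mesh.n_vertices)
    for sign in ("+", "-"):
        same = [p for p in patches if p.sign == sign]
        seen = set()
        for p in same:
            members = set(int(v) for v in p.vertex_ids)
            assert not members & seen, "same-sign patches overlap"
            seen |= members
            vals = mesh.vertex_value[p.vertex_ids]
            if sign == "+":
                assert np.all(vals >= params.positive_isovalue)
            else:
                assert np.all(vals <= params.negative_isovalue)
            # maximality: no neighbor outside the patch also qualifies
            for v in members:
                for w in adj[v]:
                    if w in members:
                        continue
                    val = mesh.vertex_value[w]
                    ok = (val >= params.positive_isovalue if sign == "+"
                          else val <= params.negative_isovalue)
                    assert not ok, "patch is not maximal"
        areas = [p.area for p in same]
        assert areas == sorted(areas, reverse=True)
        assert [p.rank for p in same] == list(range(1, len(same) + 1))


class TestSegmentation:
    def test_all_vertices_positive_gives_one_full_patch(self):
        mesh = make_labeled_mesh(seed=0, n_vertices=100)
        mesh.vertex_value = np.full(mesh.n_vertices, 2.0)
        patches = segment_patches(mesh, PatchParams())
        assert len(patches) == 1
        p = patches[0]
        assert p.sign == "+" and p.rank == 1
        assert p.n_vertices == mesh.n_vertices
        assert p.area == pytest.approx(mesh.total_area)

    def test_values_inside_band_give_no_patches(self):
        mesh = make_labeled_mesh(seed=0, n_vertices=100)
        mesh.vertex_value = np.random.default_rng(0).uniform(
            -0.49, 0.49, mesh.n_vertices
        )
        assert segment_patches(mesh, PatchParams()) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_flood_fill_oracle(self, seed):
        mesh = make_labeled_mesh(seed=seed, n_vertices=500 + 75 * seed)
        params = PatchParams(positive_isovalue=0.5, negative_isovalue=-0.5)
        patches = segment_patches(mesh, params)
        adj = mesh_adjacency(mesh.triangles, mesh.n_vertices)
        for sign, mask in (
            ("+", mesh.vertex_value >= 0.5),
            ("-", mesh.vertex_value <= -0.5),
        ):
            expected = flood_fill_components(mask, adj)
            got = sorted(
                (list(map(int, p.vertex_ids)) for p in patches if p.sign == sign)
            )
            assert sorted(expected) == got
            # areas agree member-by-member
            for comp in expected:
                area = mesh.vertex_area[comp].sum()
                match = [p for p in patches
                         if p.sign == sign and list(p.vertex_ids) == comp]
                assert len(match) == 1
                assert match[0].area == pytest.approx(area, rel=1e-12)
        assert_patch_invariants(patches, mesh, params)

    @pytest.mark.parametrize("seed", [1, 5, 11])
    def test_sign_antisymmetry(self, seed):
        mesh = make_labeled_mesh(seed=seed)
        params = PatchParams(positive_isovalue=0.5, negative_isovalue=-0.5)
        pos_patches = [p for p in segment_patches(mesh, params) if p.sign == "+"]
        mesh.vertex_value = -mesh.vertex_value
        neg_patches = [p for p in segment_patches(mesh, params) if p.sign == "-"]
        assert len(pos_patches) == len(neg_patches)
        for a, b in zip(pos_patches, neg_patches):
            np.testing.assert_array_equal(a.vertex_ids, b.vertex_ids)
            assert a.area == pytest.approx(b.area)

    @pytest.mark.parametrize("seed", [2, 9])
    def test_raising_isolevel_shrinks_positive_area(self, seed):
        mesh = make_labeled_mesh(seed=seed)
        areas = []
        for iso in (0.2, 0.6, 1.0, 1.4):
            patches = segment_patches(
                mesh, PatchParams(positive_isovalue=iso, negative_isovalue=-2.5)
            )
            areas.append(sum(p.area for p in patches if p.sign == "+"))
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestFiltering:
    def _patches(self, mesh, **kw):
        return segment_patches(mesh, PatchParams(**kw))

    def test_min_area_threshold(self):
        mesh = make_labeled_mesh(seed=4)
        patches = self._patches(mesh)
        cutoff = np.median([p.area for p in patches])
        kept = filter_patches(patches, PatchParams(min_area=cutoff))
        assert kept
        assert all(p.area >= cutoff for p in kept)

    def test_max_patches_keeps_largest_per_sign(self):
        mesh = make_labeled_mesh(seed=4)
        patches = self._patches(mesh)
        kept = filter_patches(patches, PatchParams(max_patches=1))
        assert {p.sign for p in kept} <= {"+", "-"}
        for sign in ("+", "-"):
            sub = [p for p in kept if p.sign == sign]
            allp = [p for p in patches if p.sign == sign]
            if allp:
                assert len(sub) == 1
                assert sub[0].area == max(p.area for p in allp)
                assert sub[0].rank == 1

    def test_permissive_filter_is_identity(self):
        mesh = make_labeled_mesh(seed=4)
        patches = self._patches(mesh)
        kept = filter_patches(patches, PatchParams())
        assert len(kept) == len(patches)
        assert {id(p) for p in kept} == {id(p) for p in patches}


def two_residue_structure():
    mk = lambda i, resnum: Atom(
        serial=i, name="X", residue_name="AAA" if resnum == 1 else "BBB",
        chain_id="A", residue_number=resnum, position=np.zeros(3),
        charge=0.0, radius=1.5,
    )
    return Structure(atoms=[mk(1, 1), mk(2, 2)])


class TestSummary:
    def hand_mesh(self):
        # 6 vertices, two triangle fans, areas chosen by hand
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0], [3, 0, 0], [2, 1, 0]],
            dtype=float,
        )
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        areas = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        mesh = SurfaceMesh(vertices=verts, triangles=tris, vertex_area=areas)
        mesh.vertex_value = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        # vertices 0-2 belong to residue 1's atom, 3-5 to residue 2's
        mesh.nearest_atom = np.array([0, 0, 0, 1, 1, 1])
        return mesh

    def test_top_residue_by_hand(self):
        mesh = self.hand_mesh()
        structure = two_residue_structure()
        patches = segment_patches(mesh, PatchParams())
        # two disconnected components, both positive
        assert len(patches) == 2
        table = summarize_patches(patches, mesh, structure)
        # rank 1 = larger fan (vertices 3-5, residue 2, area 6)
        assert table.iloc[0]["area_A2"] == pytest.approx(6.0)
        assert table.iloc[0]["top_residue_number"] == 2
        assert table.iloc[0]["top_residue_name"] == "BBB"
        assert table.iloc[1]["area_A2"] == pytest.approx(3.0)
        assert table.iloc[1]["top_residue_number"] == 1

    def test_marked_residues_flag(self):
        mesh = self.hand_mesh()
        structure = two_residue_structure()
        patches = segment_patches(mesh, PatchParams())
        table = summarize_patches(patches, mesh, structure,
                                  marked_residues={("A", 2)})
        flagged = dict(zip(table["top_residue_number"],
                           table["contains_marked_residue"]))
        assert flagged[2] and not flagged[1]

    def test_empty_marked_set_flags_nothing(self):
        mesh = self.hand_mesh()
        patches = segment_patches(mesh, PatchParams())
        table = summarize_patches(patches, mesh, two_residue_structure(), set())
        assert not table["contains_marked_residue"].any()

    def test_missing_attribution_is_an_error(self):
        mesh = self.hand_mesh()
        mesh.nearest_atom = None
        patches = segment_patches(mesh, PatchParams())
        with pytest.raises(ValueError, match="attribute_vertices"):
            summarize_patches(patches, mesh, two_residue_structure())


def test_patch_vertex_labels_partition():
    mesh = make_labeled_mesh(seed=6)
    patches = segment_patches(mesh, PatchParams())
    labels = patch_vertex_labels(patches, mesh.n_vertices)
    for i, p in enumerate(patches):
        assert np.all(labels[p.vertex_ids] == i)
    unpatched = np.flatnonzero(labels == -1)
    members = set(int(v) for p in patches for v in p.vertex_ids)
    assert members.isdisjoint(unpatched)
    assert len(members) + len(unpatched) == mesh.n_vertices
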