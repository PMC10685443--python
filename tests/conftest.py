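import numpy as np
import pytest

from surfpatch import GridSpec, ScalarGrid
from surfpatch.synthetic import toy_peptide


@pytest.fixture(scope="session")
def peptide():
    return toy_peptide()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_grid(rng, shape=(4, 5, 6), spacing=(1.0, 1.0, 1.0), unit="kT/e"):
    spec = GridSpec(
        origin=rng.uniform(-5, 5, size=3),
        spacing=np.asarray(spacing, dtype=float),
        shape=shape,
    )
    return ScalarGrid(spec, rng.normal(size=shape), unit=unit)


def mesh_adjacency(triangles, n_vertices):
    """Vertex adjacency sets from triangle edges (oracle helper)."""
    adj = [set() for _ in range(n_vertices)]
    for a, b, c in triangles:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return adj


def flood_fill_components(member_mask, adjacency):
    """Breadth-first connected components of the induced subgraph.

    Independent reference for the patch segmentation: plain Python BFS with
    no shared code with the implementation.
    """
    from collections import deque

    seen = set()
    components = []
    for start in range(len(member_mask)):
        if not member_mask[start] or start in seen:
            continue
        comp = []
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            comp.append(v)
            for w in adjacency[v]:
                if member_mask[w] and w not in seen:
                    seen.add(w)
                    queue.append(w)
        components.append(sorted(comp))
    return components
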