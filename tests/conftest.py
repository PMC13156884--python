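"""Shared fixtures and independent oracles for the test suite.

The oracles here (iterative flood fill, networkx-based skeleton graph)
deliberately avoid the implementation's code paths so that agreement is
evidence of correctness, not of shared bugs.
"""

from __future__ import annotations

import numpy as np
import pytest

from tjmesh import MeshworkSpec, OpticsSpec, generate_geometry

OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
OFFSETS_4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Brute-force connected components via an explicit-stack flood fill.

    Returns a list of component sizes (unordered).
    """
    offsets = OFFSETS_8 if connectivity == 8 else OFFSETS_4
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    sizes = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            size = 0
            while stack:
                r, c = stack.pop()
                size += 1
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            sizes.append(size)
    return sizes


def skeleton_graph_oracle(skel: np.ndarray) -> tuple[int, int]:
    """Independent branch/junction counts from a pixel adjacency graph.

    Junctions: connected clusters of skeleton pixels with degree >= 3.
    Branches: connected chains of the remaining pixels (each chain is one
    branch, including isolated cycles), plus direct adjacencies between
    distinct junction clusters that have no chain pixels between them.
    """
    import networkx as nx

    skel = np.asarray(skel, bool)
    g = nx.Graph()
    pix = [tuple(p) for p in np.argwhere(skel)]
    g.add_nodes_from(pix)
    pixset = set(pix)
    for r, c in pix:
        for dr, dc in OFFSETS_8:
            q = (r + dr, c + dc)
            if q in pixset:
                g.add_edge((r, c), q)
    node_px = {p for p in g if g.degree(p) >= 3 or g.degree(p) == 1}
    junction_px = {p for p in g if g.degree(p) >= 3}
    clusters = list(nx.connected_components(g.subgraph(junction_px)))
    cluster_of = {}
    for i, cl in enumerate(clusters):
        for p in cl:
            cluster_of[p] = i

    # each connected chain of non-node pixels is one branch (isolated cycles
    # included); isolated single pixels (degree 0) are not branches
    interior = g.subgraph([p for p in g if p not in node_px])
    n_branches = sum(1 for comp in nx.connected_components(interior)
                     if any(g.degree(p) > 0 for p in comp))
    # plus direct node-node adjacencies with no chain pixels in between
    # (two junction pixels of the same cluster are one node, not a branch)
    direct = set()
    for p in node_px:
        for q in g.neighbors(p):
            if q in node_px and not (p in junction_px and q in junction_px
                                     and cluster_of[p] == cluster_of[q]):
                direct.add(frozenset((p, q)))
    return n_branches + len(direct), len(clusters)


@pytest.fixture(scope="session")
def default_truth():
    """One deterministic ground-truth meshwork shared by read-only tests."""
    return generate_geometry(MeshworkSpec(seed=3))


@pytest.fixture(scope="session")
def sted_optics():
    return OpticsSpec.sted_default(photons_per_strand_px=50,
                                   background_photons_per_px=1.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
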