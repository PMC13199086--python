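"""Skeleton graphs, trunk identification, and hierarchical branch levels.

The skeleton of each vessel component is turned into a voxel graph
(nodes = skeleton voxels, edges = 26-adjacent pairs weighted by physical
length).  The *trunk* (primary vessel path) of a component is its
maximum-physical-length simple path, computed exactly as the diameter of
a minimum spanning tree via two farthest-node sweeps.  Branch levels are
then reconstructed outward level by level: removing the trunk leaves
remainder components; in each, the longest path starting from its
attachment to the previous level becomes the next-level branch, and the
peeling repeats until every skeleton voxel carries exactly one level —
no voxel is ever relabeled (exclusion constraint).

This mirrors the qualitative color taxonomy used for QA renders: trunk
red, first-order branches green, second-order blue, higher orders
magenta, tumor overlay purple.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ValidationError
from .grids import BinaryMask, BranchLabelVolume

#: Fig-style QA color scheme: level -> RGB in [0, 1].
COLOR_SCHEME = {
    0: (1.0, 0.0, 0.0),  # trunk: red
    1: (0.0, 1.0, 0.0),  # first-order: green
    2: (0.0, 0.0, 1.0),  # second-order: blue
    3: (1.0, 0.0, 1.0),  # higher-order: magenta (levels >= 3 collapse here)
}
TUMOR_COLOR = (0.5, 0.0, 0.5)  # purple

_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_HALF_OFFSETS = [o for o in _OFFSETS if o > (0, 0, 0)]


def _lex_key(node: tuple[int, int, int]) -> tuple[int, int, int]:
    # all tie-breaks in this module are lexicographic on (z, y, x)
    x, y, z = node
    return (z, y, x)


@dataclass
class SkeletonGraph:
    """Voxel-resolution centerline graph.

    graph : networkx.Graph with voxel-coordinate nodes ``(x, y, z)`` and
        ``length`` edge attributes in mm.
    shape, spacing, affine : geometry of the originating grid.
    components : list of frozensets of nodes, sorted by (size desc,
        lex-smallest node) so ``components[0]`` is the largest.
    """

    graph: nx.Graph
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray
    components: list[frozenset]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def skeleton_to_graph(skeleton: BinaryMask) -> SkeletonGraph:
    """Build the 26-adjacency graph of skeleton voxels with mm edge lengths."""
    sx, sy, sz = skeleton.spacing
    coords = np.argwhere(skeleton.data)
    g = nx.Graph()
    g.add_nodes_from(map(tuple, coords.tolist()))
    occupied = set(g.nodes)
    for dx, dy, dz in _HALF_OFFSETS:
        length = float(np.sqrt((dx * sx) ** 2 + (dy * sy) ** 2 + (dz * sz) ** 2))
        for x, y, z in occupied:
            nb = (x + dx, y + dy, z + dz)
            if nb in occupied:
                g.add_edge((x, y, z), nb, length=length)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(map(_lex_key, c))))
    return SkeletonGraph(g, skeleton.shape, skeleton.spacing, np.asarray(skeleton.affine), comps)


def _component_mst(graph: nx.Graph, component: frozenset) -> nx.Graph:
    """Kruskal MST with deterministic ties: length, then lexicographic endpoints."""
    sub = graph.subgraph(component)
    edges = sorted(
        sub.edges(data="length"),
        key=lambda e: (e[2], min(_lex_key(e[0]), _lex_key(e[1])), max(_lex_key(e[0]), _lex_key(e[1]))),
    )
    uf = nx.utils.UnionFind(component)
    mst = nx.Graph()
    mst.add_nodes_from(component)
    for u, v, length in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            mst.add_edge(u, v, length=length)
    return mst

def _farthest(tree: nx.Graph, source) -> tuple[tuple, dict, dict]:
    """Weighted farthest node from source; ties -> lexicographically smallest."""
    dist, paths = nx.single_source_dijkstra(tree, source, weight="length")
    far = min(dist, key=lambda n: (-dist[n], _lex_key(n)))
    return far, dist, paths


def identify_trunk(skel: SkeletonGraph, component: frozenset) -> list[tuple[int, int, int]]:
    """Maximum-physical-length simple path of a component (exact tree diameter).

    Computed on the component's minimum spanning tree via two
    farthest-node sweeps; returned as an ordered voxel sequence.
    """
    if not component:
        raise ValidationError("empty skeleton component")
    if len(component) == 1:
        return [next(iter(component))]
    mst = _component_mst(skel.graph, component)
    start = min(component, key=_lex_key)
    end_a, _, _ = _farthest(mst, start)
    end_b, _, paths = _farthest(mst, end_a)
    path = paths[end_b]
    # orient deterministically: lexicographically smaller endpoint first
    if _lex_key(path[-1]) < _lex_key(path[0]):
        path = path[::-1]
    return path


def _principal_path(
    sub: nx.Graph, attachments: list[tuple]
) -> list[tuple]:
    """Longest path in ``sub`` starting at one of ``attachments`` (mm-weighted)."""
    dist, paths = nx.multi_source_dijkstra(sub, set(attachments), weight="length")
    far = min(dist, key=lambda n: (-dist[n], _lex_key(n)))
    return paths[far]


def propagate_branch_levels(
    skel: SkeletonGraph, trunks: dict[int, list[tuple]]
) -> BranchLabelVolume:
    """Level-by-level branch reconstruction under the exclusion constraint.

    Trunk voxels get level 0.  Repeatedly: among yet-unlabeled voxels,
    each connected remainder part adjacent to labeled voxels receives the
    level one above the smallest adjacent label, applied along its
    principal path (longest path from the attachment); remaining voxels of
    the part are picked up in later rounds.  Every voxel is labeled
    exactly once.
    """
    out = np.full(skel.shape, -1, dtype=np.int16)
    for ci, component in enumerate(skel.components):
        trunk = trunks[ci]
        level: dict[tuple, int] = {v: 0 for v in trunk}
        unlabeled = set(component) - set(trunk)
        graph = skel.graph
        guard = 0
        while unlabeled:
            guard += 1
            if guard > len(component) + 1:
                raise AssertionError("branch-level propagation failed to converge")
            sub_all = graph.subgraph(unlabeled)
            parts = sorted(
                (frozenset(p) for p in nx.connected_components(sub_all)),
                key=lambda p: min(map(_lex_key, p)),
            )
            newly: dict[tuple, int] = {}
            for part in parts:
                # labeled neighbours of this remainder part, and the level to assign
                adj_levels: dict[tuple, int] = {}
                for v in part:
                    for nb in graph.neighbors(v):
                        if nb in level:
                            adj_levels[v] = min(adj_levels.get(v, 10**9), level[nb])
                if not adj_levels:
                    continue  # not yet reachable; a later round exposes it
                k = min(adj_levels.values()) + 1
                attachments = sorted(
                    (v for v, lv in adj_levels.items() if lv == k - 1), key=_lex_key
                )
                path = _principal_path(graph.subgraph(part), attachments)
                for v in path:
                    assert v not in level and v not in newly  # exclusion constraint
                    newly[v] = k
            if not newly:
                raise AssertionError("branch-level propagation stalled on a connected component")
            level.update(newly)
            unlabeled -= set(newly)
        for (x, y, z), lv in level.items():
            out[x, y, z] = lv
    main = 0 if skel.components else None
    return BranchLabelVolume(out, skel.spacing, skel.affine, main_component=main)


def label_branches(skeleton: BinaryMask) -> tuple[BranchLabelVolume, SkeletonGraph, dict[int, list]]:
    """Convenience: graph -> per-component trunks -> branch-level volume."""
    skel = skeleton_to_graph(skeleton)
    trunks = {ci: identify_trunk(skel, comp) for ci, comp in enumerate(skel.components)}
    labels = propagate_branch_levels(skel, trunks)
    return labels, skel, trunks


def colorize_labels(
    labels: BranchLabelVolume,
    tumor: BinaryMask | None = None,
    scheme: dict[int, tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """RGB overlay volume: trunk red, level-1 green, level-2 blue, >=3 magenta,
    tumor purple underneath (vessel color wins at overlaps)."""
    scheme = scheme or COLOR_SCHEME
    out = np.zeros(labels.shape + (3,), dtype=np.float32)
    if tumor is not None:
        if tumor.shape != labels.shape:
            raise ValidationError("tumor mask grid does not match label volume")
        out[tumor.data] = TUMOR_COLOR
    data = labels.data
    for lv, color in scheme.items():
        if lv < 3:
            sel = data == lv
        else:
            sel = data >= 3
        out[sel] = color
    return out


def component_summary(
    labels: BranchLabelVolume, skel: SkeletonGraph, trunks: dict[int, list]
) -> "pd.DataFrame":
    """Per-component table: voxels, trunk length (mm), per-level voxel counts."""
    import pandas as pd

    sx, sy, sz = skel.spacing
    rows = []
    for ci, comp in enumerate(skel.components):
        trunk = trunks[ci]
        tlen = 0.0
        for u, v in zip(trunk, trunk[1:]):
            tlen += skel.graph.edges[u, v]["length"]
        levels = [labels.data[x, y, z] for (x, y, z) in comp]
        counts = np.bincount(np.asarray(levels, dtype=int), minlength=4)
        rows.append(
            {
                "component": ci,
                "is_main_trunk": ci == labels.main_component,
                "voxels": len(comp),
                "trunk_length_mm": tlen,
                "level0_voxels": int(counts[0]),
                "level1_voxels": int(counts[1]),
                "level2_voxels": int(counts[2]),
                "level3plus_voxels": int(counts[3:].sum()),
            }
        )
    return pd.DataFrame(rows)
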