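"""Growth-cone morphometry from an actin-outline mask.

Five metrics per growth cone: area (um^2), perimeter (um), elongation
ratio (major/minor axis of the second-moment best-fit ellipse), longest
shortest path (LSP — the maximum geodesic distance between any two
skeleton nodes), and filopodia count (terminal skeleton branches longer
than a minimum length, 1.0 um by default).

The mask is expected to contain exactly one connected component: the
caller isolates the growth cone and excludes the axon shaft.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage import measure, morphology

from .types import BinaryMask

__all__ = ["GCParams", "Skeleton", "GCMetrics", "region_metrics",
           "skeletonize_mask", "skeleton_metrics", "prune_skeleton",
           "measure_growth_cone"]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class GCParams:
    """Skeleton-metric parameters.

    ``min_filopodium_len_um``: a terminal branch counts as a filopodium
    only beyond this geodesic length (default 1.0 um).
    ``prune_len_um``: spurs shorter than this are removed before any
    counting (default 0.5 um); must stay below the filopodium threshold.
    """

    min_filopodium_len_um: float = 1.0
    prune_len_um: float = 0.5
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.prune_len_um < self.min_filopodium_len_um):
            raise ValueError("need 0 < prune_len_um < min_filopodium_len_um")
        if self.connectivity != 8:
            raise ValueError("skeleton graphs use 8-connectivity")


@dataclass
class Skeleton:
    """Condensed graph of a 1-px-wide thinning.

    Nodes are skeleton pixels of degree != 2 (endpoints, junctions,
    isolated pixels), keyed by (row, col); edges are the pixel chains
    between them with geodesic length in um (unit steps count the pixel
    size, diagonal steps sqrt(2) times it).
    """

    graph: nx.MultiGraph
    pixel_size_um: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def endpoints(self) -> list:
        return [n for n in self.graph if self.graph.degree(n) == 1]

    def junctions(self) -> list:
        return [n for n in self.graph if self.graph.degree(n) >= 3]


@dataclass
class GCMetrics:
    area_um2: float
    perimeter_um: float
    elongation_ratio: float
    lsp_um: float
    n_filopodia: int


def _single_label(mask: BinaryMask) -> np.ndarray:
    if not mask.values.any():
        raise ValueError("mask is empty")
    labels = measure.label(mask.values, connectivity=2)
    if labels.max() != 1:
        raise ValueError(
            f"mask has {labels.max()} connected components; isolate the growth cone first")
    return labels


def region_metrics(mask: BinaryMask) -> tuple[float, float, float]:
    """(area_um2, perimeter_um, elongation_ratio) of a single-component mask.

    Area is the foreground pixel count times the pixel area.  Perimeter
    is the polygon length of the outer marching-squares contour, which
    converges to the analytic perimeter for smooth shapes.  Elongation
    is the major/minor axis ratio of the equal-second-moment ellipse.
    """
    labels = _single_label(mask)
    area = float(mask.values.sum()) * mask.calibration.pixel_area_um2
    px = mask.calibration.pixel_size_um
    contours = measure.find_contours(mask.values.astype(float), 0.5)
    outer = max(contours, key=lambda c: len(c))
    perim = float(np.hypot(*np.diff(outer, axis=0).T).sum()) * px
    props = measure.regionprops(labels)[0]
    minor = props.axis_minor_length
    if minor == 0:
        raise ValueError("degenerate region: zero minor axis")
    elong = float(props.axis_major_length / minor)
    return area, perim, elong


_OFFS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeletonize_mask(mask: BinaryMask) -> Skeleton:
    """Topology-preserving thinning condensed into a node/edge graph."""
    _single_label(mask)
    px = mask.calibration.pixel_size_um
    skel = morphology.skeletonize(mask.values)
    pixels = set(zip(*np.nonzero(skel)))
    if not pixels:
        raise ValueError("skeletonization produced an empty skeleton")

    def neighbors(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _OFFS
                if (p[0] + dr, p[1] + dc) in pixels]

    deg = {p: len(neighbors(p)) for p in pixels}
    nodes = {p for p, d in deg.items() if d != 2}
    g = nx.MultiGraph()
    for p in nodes:
        g.add_node(p)
    visited_steps: set[tuple] = set()

    def step_len(a, b) -> float:
        return _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0

    def walk(start, first):
        """Follow a degree-2 chain from a node until the next node."""
        length = step_len(start, first)
        prev, cur = start, first
        while cur not in nodes:
            nbrs = [q for q in neighbors(cur) if q != prev]
            # at a corner a degree-2 pixel can see the previous pixel's
            # neighbor too; pick the one continuing the chain
            nxt = nbrs[0]
            length += step_len(cur, nxt)
            prev, cur = cur, nxt
        return cur, length

    for p in sorted(nodes):
        for q in neighbors(p):
            if (p, q) in visited_steps:
                continue
            end, length = walk(p, q)
            # mark both directions of the chain's terminal steps as used
            visited_steps.add((p, q))
            # re-walk to mark the closing step from the far side
            prev, cur = p, q
            while cur not in nodes:
                nbrs = [r for r in neighbors(cur) if r != prev]
                prev, cur = cur, nbrs[0]
            visited_steps.add((cur, prev))
            g.add_edge(p, end, length=length * px)
    # isolated cycles (all pixels degree 2): promote one pixel per cycle
    remaining = {p for p in pixels if deg[p] == 2}
    # remove chain pixels reachable from nodes
    seen = set()
    for p in nodes:
        stack = [p]
        while stack:
            cur = stack.pop()
            for q in neighbors(cur):
                if q not in seen and q not in nodes:
                    seen.add(q)
                    stack.append(q)
    remaining -= seen
    while remaining:
        p = min(remaining)
        nodes.add(p)
        g.add_node(p)
        nbrs = neighbors(p)
        end, length = walk(p, nbrs[0])
        g.add_edge(p, end, length=length * px)
        # drop the whole cycle from remaining
        stack = [p]
        remaining.discard(p)
        comp = {p}
        while stack:
            cur = stack.pop()
            for q in neighbors(cur):
                if q in remaining:
                    remaining.discard(q)
                    comp.add(q)
                    stack.append(q)
    return Skeleton(graph=g, pixel_size_um=px)


def _merge_degree2(g: nx.MultiGraph) -> None:
    """Collapse degree-2 non-self-loop nodes, summing edge lengths."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) == 2 and not any(u == v for u, v, _ in g.edges(n, keys=True)):
                edges = list(g.edges(n, keys=True, data=True))
                if len(edges) != 2:
                    continue
                (_, a, _, da), (_, b, _, db) = edges
                if a == n or b == n:
                    continue
                g.remove_node(n)
                g.add_edge(a, b, length=da["length"] + db["length"])
                changed = True


def prune_skeleton(skel: Skeleton, prune_len_um: float) -> Skeleton:
    """Remove terminal spurs shorter than ``prune_len_um``.

    Iterates to a fixed point (so pruning is idempotent), then collapses
    any junction left with degree 2.
    """
    g = skel.graph.copy()
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) == 1:
                (_, other, key) = next(iter(g.edges(n, keys=True)))
                if g.degree(other) >= 3 and g.edges[n, other, key]["length"] < prune_len_um:
                    g.remove_node(n)
                    changed = True
        if changed:
            _merge_degree2(g)
    return Skeleton(graph=g, pixel_size_um=skel.pixel_size_um)


def longest_shortest_path(skel: Skeleton) -> float:
    """Maximum over node pairs of the geodesic distance along edges."""
    g = skel.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty skeleton")
    if not nx.is_connected(g):
        raise ValueError("disconnected skeleton: upstream mask error")
    best = 0.0
    for n in g.nodes:
        dist = nx.single_source_dijkstra_path_length(g, n, weight="length")
        m = max(dist.values())
        best = max(best, m)
    return float(best)


def skeleton_metrics(skel: Skeleton, params: GCParams | None = None
                     ) -> tuple[float, int]:
    """(lsp_um, n_filopodia) after spur pruning.

    A filopodium is a terminal edge running from a junction (degree >= 3)
    to an endpoint, longer than the minimum filopodium length; a
    junction-free skeleton therefore has zero filopodia.
    """
    params = params or GCParams()
    pruned = prune_skeleton(skel, params.prune_len_um)
    lsp = longest_shortest_path(pruned)
    g = pruned.graph
    n_filo = 0
    for n in g.nodes:
        if g.degree(n) == 1:
            (_, other, key) = next(iter(g.edges(n, keys=True)))
            if g.degree(other) >= 3 and \
                    g.edges[n, other, key]["length"] > params.min_filopodium_len_um:
                n_filo += 1
    return lsp, n_filo


def measure_growth_cone(mask: BinaryMask, params: GCParams | None = None) -> GCMetrics:
    """All five morphometrics for one growth-cone mask."""
    area, perim, elong = region_metrics(mask)
    skel = skeletonize_mask(mask)
    lsp, n_filo = skeleton_metrics(skel, params)
    return GCMetrics(area_um2=area, perimeter_um=perim, elongation_ratio=elong,
                     lsp_um=lsp, n_filopodia=n_filo)
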