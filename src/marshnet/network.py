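"""Channel-network extraction and geometry statistics for marsh DTMs.

Pipeline: a channel mask is detected by median-neighborhood analysis
(pixels lying more than a threshold below the local median), the mask is
thinned to a centerline skeleton, the skeleton becomes a node/section graph
oriented away from the outlet, and per-point quantities (upstream lengths,
D8 watershed areas, Hack stream orders) feed the summary statistics:
stream counts and bifurcation ratios per order, Hortonian drainage density,
exceedance curves of watershed area and unchanneled path length, two-sample
Kolmogorov-Smirnov similarity between networks, and the elevation-
vegetation pattern correlation.

Hack's ordering is used throughout: the main channel is order 1 and the
tributaries of an order-i stream are order i+1, so *higher* order means
*finer* scale — the opposite reading from Strahler ordering.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage, stats
from skimage.morphology import disk, skeletonize as _skimage_skeletonize

__all__ = [
    "DTMRaster",
    "ChannelMask",
    "Skeleton",
    "Section",
    "NetworkStats",
    "detect_channels",
    "unchanneled_path_length",
    "skeletonize",
    "orient_skeleton",
    "watershed_areas",
    "hack_order",
    "bifurcation_ratios",
    "hortonian_drainage_density",
    "exceedance",
    "exceedance_at",
    "ks_similarity",
    "pattern_correlation",
    "fill_depressions",
    "flow_accumulation",
    "network_statistics",
    "analyze_dtm",
    "skeleton_from_sections",
]


# ---------------------------------------------------------------------------
# Raster containers
# ---------------------------------------------------------------------------

@dataclass
class DTMRaster:
    """Digital terrain model: elevation grid (m) with square pixels.

    ``nodata`` is an optional boolean grid marking missing cells (True =
    missing); missing cells are excluded from neighborhood medians and
    never flagged as channel.
    """

    elevation: np.ndarray
    pixel_size: float
    nodata: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError(f"pixel size must be > 0, got {self.pixel_size}")
        if self.nodata is not None:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.elevation.shape:
                raise ValueError("nodata mask shape mismatch")
        valid = (self.elevation if self.nodata is None
                 else self.elevation[~self.nodata])
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("non-finite elevations outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def area(self) -> float:
        """Total raster area (m^2), counting only valid pixels."""
        n = (self.elevation.size if self.nodata is None
             else int((~self.nodata).sum()))
        return n * self.pixel_size ** 2


@dataclass
class ChannelMask:
    """Boolean channel-pixel grid aligned with its source DTM."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Channel detection and distance transform
# ---------------------------------------------------------------------------

def detect_channels(dtm: DTMRaster, window_radius: float,
                    depth_threshold: float) -> ChannelMask:
    """Median-neighborhood channel detection.

    A pixel is flagged as channel iff its elevation lies more than
    ``depth_threshold`` below the median elevation within a circular window
    of radius ``window_radius`` (both in metres). The window must span at
    least one pixel. No hidden defaults: suitable values depend on channel
    depth and spacing and must be chosen per dataset.
    """
    r_px = int(round(window_radius / dtm.pixel_size))
    if r_px < 1:
        raise ValueError(
            f"window_radius {window_radius} is smaller than one pixel "
            f"({dtm.pixel_size})")
    footprint = disk(r_px)
    if dtm.nodata is None:
        med = ndimage.median_filter(dtm.elevation, footprint=footprint,
                                    mode="nearest")
        mask = (dtm.elevation - med) < -depth_threshold
    else:
        elev = np.where(dtm.nodata, np.nan, dtm.elevation)
        med = ndimage.generic_filter(elev, np.nanmedian,
                                     footprint=footprint, mode="nearest")
        mask = ((dtm.elevation - med) < -depth_threshold) & ~dtm.nodata
    return ChannelMask(mask, dtm.pixel_size)


def unchanneled_path_length(mask: ChannelMask) -> np.ndarray:
    """Euclidean distance (m) from every pixel to the nearest channel
    pixel; zero on channel pixels. Exact distance transform."""
    if not mask.mask.any():
        raise ValueError("mask contains no channel pixels")
    return ndimage.distance_transform_edt(~mask.mask) * mask.pixel_size


# ---------------------------------------------------------------------------
# Skeleton graph
# ---------------------------------------------------------------------------

_NEIGHBORS8 = [(-1, 0), (1, 0), (0, -1), (0, 1),
               (-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass
class Section:
    """A skeleton centerline between two nodes.

    ``pixels`` is the ordered pixel path (downstream to upstream once the
    skeleton is oriented); ``points`` are the equidistant resampled points
    (row, col in pixel coordinates, float) with ``point_arc`` their
    arclength from the downstream end. Hack ``order`` and ``subbasin``
    identifier are filled by :func:`hack_order`, the per-point upstream
    lengths by :func:`orient_skeleton` and ``area`` by
    :func:`watershed_areas`.
    """

    id: int
    start_node: int
    end_node: int
    pixels: np.ndarray
    length: float
    points: np.ndarray = field(default=None, repr=False)
    point_arc: np.ndarray = field(default=None, repr=False)
    upstream_max_length: np.ndarray | None = None
    upstream_total_length: np.ndarray | None = None
    area: np.ndarray | None = None
    order: int | None = None
    subbasin: int | None = None


@dataclass
class Skeleton:
    """Centerline graph of a channel network.

    ``graph`` is an undirected multigraph whose nodes are junction/head/
    outlet identifiers (attribute ``rc``: representative pixel) and whose
    edges carry a ``section`` index into ``sections``. Orientation
    (downstream node first), node kinds and outlet choice are set by
    :func:`orient_skeleton`.
    """

    graph: nx.MultiGraph
    sections: list[Section]
    pixel_size: float
    shape: tuple[int, int]
    spacing: float = 0.5
    outlets: list[int] = field(default_factory=list)
    n_cycle_edges_removed: int = 0

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.sections)

    def node_kind(self, n: int) -> str:
        return self.graph.nodes[n].get("kind", "junction")

    def points_with(self, attr: str) -> np.ndarray:
        """Concatenate a per-point attribute over all sections."""
        vals = [getattr(s, attr) for s in self.sections
                if getattr(s, attr) is not None]
        if not vals:
            return np.array([])
        return np.concatenate(vals)

    def consistency_check(self) -> None:
        for s in self.sections:
            if s.start_node not in self.graph or s.end_node not in self.graph:
                raise AssertionError("dangling section end")
            if s.order is not None and s.order < 1:
                raise AssertionError("Hack orders must be >= 1")


def _resample(path_px: np.ndarray, pixel_size: float,
              spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Equidistant points along a pixel polyline; returns (points, arcs)."""
    if len(path_px) == 1:
        return path_px.astype(float), np.array([0.0])
    seg = np.sqrt((np.diff(path_px, axis=0) ** 2).sum(axis=1)) * pixel_size
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = cum[-1]
    arcs = np.arange(0.0, L + 1e-9, spacing)
    rows = np.interp(arcs, cum, path_px[:, 0])
    cols = np.interp(arcs, cum, path_px[:, 1])
    return np.column_stack([rows, cols]), arcs


def _path_length(path_px: np.ndarray, pixel_size: float) -> float:
    if len(path_px) < 2:
        return 0.0
    seg = np.sqrt((np.diff(path_px, axis=0) ** 2).sum(axis=1))
    return float(seg.sum()) * pixel_size


def skeletonize(mask: ChannelMask, *, prune_factor: float = 2.0,
                spacing: float = 0.5) -> Skeleton:
    """Thin the channel mask to centerlines and build the section graph.

    Node pixels are skeleton pixels with a number of 8-neighbors different
    from two (channel heads, junctions, isolated pixels); adjacent node
    pixels are clustered into a single node. Spur sections shorter than
    ``prune_factor`` times the pixel size are removed (skeletonization
    artifacts), after which pass-through nodes are merged away. Every
    section is resampled at ``spacing``-metre equidistant points.
    """
    img = mask.mask
    if not img.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = _skimage_skeletonize(img)

    nbr_count = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3)),
                                 mode="constant") - skel.astype(np.uint8)
    node_px = skel & (nbr_count != 2)
    # components without any node pixel are pure cycles: cut at one pixel
    comp_lab, n_comp = ndimage.label(skel, structure=np.ones((3, 3)))
    for c in range(1, n_comp + 1):
        comp = comp_lab == c
        if not (node_px & comp).any():
            rr, cc = np.nonzero(comp)
            node_px[rr[0], cc[0]] = True

    node_lab, n_nodes = ndimage.label(node_px, structure=np.ones((3, 3)))

    G = nx.MultiGraph()
    in_skel = lambda r, c: (0 <= r < skel.shape[0] and 0 <= c < skel.shape[1]
                            and skel[r, c])
    for nid in range(1, n_nodes + 1):
        rr, cc = np.nonzero(node_lab == nid)
        cen = (rr.mean(), cc.mean())
        k = int(np.argmin((rr - cen[0]) ** 2 + (cc - cen[1]) ** 2))
        G.add_node(nid, rc=(int(rr[k]), int(cc[k])))

    sections: list[Section] = []
    visited = np.zeros_like(skel, dtype=bool)
    seen_direct: set[tuple] = set()

    def add_section(path: list[tuple[int, int]], a: int, b: int) -> None:
        arr = np.asarray(path)
        sec = Section(id=len(sections), start_node=a, end_node=b,
                      pixels=arr, length=_path_length(arr, mask.pixel_size))
        G.add_edge(a, b, section=sec.id)
        sections.append(sec)

    node_rr, node_cc = np.nonzero(node_px)
    for r0, c0 in zip(node_rr, node_cc):
        a = int(node_lab[r0, c0])
        for dr, dc in _NEIGHBORS8:
            r, c = r0 + dr, c0 + dc
            if not in_skel(r, c):
                continue
            if node_px[r, c]:
                b = int(node_lab[r, c])
                if b != a:
                    key = (min(a, b), max(a, b),
                           min((r0, c0), (r, c)), max((r0, c0), (r, c)))
                    if key not in seen_direct:
                        seen_direct.add(key)
                        add_section([(r0, c0), (r, c)], a, b)
                continue
            if visited[r, c]:
                continue
            # walk the degree-2 chain until the next node pixel
            path = [(r0, c0), (r, c)]
            visited[r, c] = True
            prev, cur = (r0, c0), (r, c)
            while True:
                nxt = None
                for dr2, dc2 in _NEIGHBORS8:
                    rr2, cc2 = cur[0] + dr2, cur[1] + dc2
                    if (rr2, cc2) == prev or not in_skel(rr2, cc2):
                        continue
                    nxt = (rr2, cc2)
                    break
                if nxt is None:          # dead end without a node pixel
                    b = a
                    break
                path.append(nxt)
                if node_px[nxt]:
                    b = int(node_lab[nxt])
                    break
                visited[nxt] = True
                prev, cur = cur, nxt
            add_section(path, a, b)

    out = Skeleton(graph=G, sections=sections, pixel_size=mask.pixel_size,
                   shape=img.shape, spacing=spacing)
    _prune_spurs(out, prune_factor * mask.pixel_size)
    for s in out.sections:
        s.points, s.point_arc = _resample(s.pixels, mask.pixel_size, spacing)
    return out


def _prune_spurs(skel: Skeleton, min_length: float) -> None:
    """Remove leaf sections shorter than ``min_length`` that hang off a
    junction, then merge pass-through (degree-2) nodes."""
    G = skel.graph
    changed = True
    while changed:
        changed = False
        for a, b, key, data in list(G.edges(keys=True, data=True)):
            sec = skel.sections[data["section"]]
            if sec.length >= min_length:
                continue
            leaf, other = None, None
            if G.degree(a) == 1 and G.degree(b) > 2:
                leaf, other = a, b
            elif G.degree(b) == 1 and G.degree(a) > 2:
                leaf, other = b, a
            if leaf is None:
                continue
            G.remove_edge(a, b, key)
            G.remove_node(leaf)
            changed = True
    # merge nodes that now simply pass through
    merged = True
    while merged:
        merged = False
        for n in list(G.nodes):
            if G.degree(n) != 2:
                continue
            edges = list(G.edges(n, keys=True, data=True))
            if len(edges) != 2:
                continue  # self-loop
            (a1, b1, k1, d1), (a2, b2, k2, d2) = edges
            s1 = skel.sections[d1["section"]]
            s2 = skel.sections[d2["section"]]
            o1 = b1 if a1 == n else a1
            o2 = b2 if a2 == n else a2
            if o1 == n or o2 == n:
                continue  # self-loop at n
            # p1 must end at node n, p2 must start there
            p1 = s1.pixels[::-1] if s1.start_node == n else s1.pixels
            p2 = s2.pixels if s2.start_node == n else s2.pixels[::-1]
            path = np.vstack([p1, p2[1:]])
            G.remove_edge(a1, b1, k1)
            G.remove_edge(a2, b2, k2)
            G.remove_node(n)
            sec = Section(id=len(skel.sections), start_node=o1, end_node=o2,
                          pixels=path,
                          length=_path_length(path, skel.pixel_size))
            skel.sections.append(sec)
            G.add_edge(o1, o2, section=sec.id)
            merged = True
    _compact_sections(skel)


def _compact_sections(skel: Skeleton) -> None:
    """Drop sections no longer referenced by the graph and renumber."""
    G = skel.graph
    live = {d["section"] for _, _, d in G.edges(data=True)}
    remap: dict[int, int] = {}
    new_sections = []
    for sid in sorted(live):
        remap[sid] = len(new_sections)
        new_sections.append(skel.sections[sid])
    for i, s in enumerate(new_sections):
        s.id = i
    for _, _, d in G.edges(data=True):
        d["section"] = remap[d["section"]]
    skel.sections = new_sections


# ---------------------------------------------------------------------------
# Orientation, upstream lengths, watershed areas, Hack ordering
# ---------------------------------------------------------------------------

def _component_outlet(skel: Skeleton, nodes: list[int],
                      dtm: DTMRaster | None, outlet: str) -> int:
    """Pick one outlet node per connected component.

    "open-edge": prefer nodes on the last raster row (the open outflow
    boundary of simulated marshes), then any raster-edge node, then the
    lowest node (needs a DTM), then the smallest node id.
    "boundary": raster-edge nodes first; "lowest": minimum elevation first.
    """
    n_r, n_c = skel.shape

    def on_open_edge(n):
        return skel.graph.nodes[n]["rc"][0] == n_r - 1

    def on_edge(n):
        r, c = skel.graph.nodes[n]["rc"]
        return r in (0, n_r - 1) or c in (0, n_c - 1)

    def elev(n):
        if dtm is None:
            return 0.0
        r, c = skel.graph.nodes[n]["rc"]
        return float(dtm.elevation[r, c])

    pools: list[list[int]] = []
    if outlet == "open-edge":
        pools = [[n for n in nodes if on_open_edge(n)],
                 [n for n in nodes if on_edge(n)]]
    elif outlet == "boundary":
        pools = [[n for n in nodes if on_edge(n)]]
    elif outlet == "lowest":
        pools = []
    else:
        raise ValueError(f"unknown outlet strategy {outlet!r}")
    for pool in pools:
        if pool:
            return min(pool, key=lambda n: (elev(n), n))
    if dtm is not None:
        return min(nodes, key=lambda n: (elev(n), n))
    return min(nodes)


def orient_skeleton(skel: Skeleton, dtm: DTMRaster | None = None,
                    outlet: str = "open-edge",
                    break_cycles: bool = True) -> Skeleton:
    """Orient every section downstream-to-upstream away from its component
    outlet and compute per-node and per-point maximum/total upstream
    lengths. Node kinds (outlet/head/junction) are assigned here.

    Braided networks produce loops in the raster skeleton; with
    ``break_cycles`` the edges closing a loop (those off the breadth-first
    orientation tree rooted at the outlet) are removed, so the result is a
    spanning drainage tree. The number of removed sections is recorded as
    ``skel.n_cycle_edges_removed``.
    """
    G = skel.graph
    skel.outlets = []
    removed: list[tuple] = []
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        out_node = _component_outlet(skel, nodes, dtm, outlet)
        skel.outlets.append(out_node)
        # BFS orientation
        order_nodes = [out_node]
        parent_edge: dict[int, tuple] = {out_node: None}
        seen = {out_node}
        queue = [out_node]
        while queue:
            cur = queue.pop(0)
            for _, nb, key, data in G.edges(cur, keys=True, data=True):
                if nb in seen:
                    continue
                seen.add(nb)
                sec = skel.sections[data["section"]]
                # orient pixels so index 0 is at the downstream (cur) end
                if sec.start_node != cur:
                    sec.pixels = sec.pixels[::-1]
                    if sec.points is not None:
                        sec.points, sec.point_arc = _resample(
                            sec.pixels, skel.pixel_size, skel.spacing)
                sec.start_node, sec.end_node = cur, nb
                parent_edge[nb] = (cur, key, data["section"])
                order_nodes.append(nb)
                queue.append(nb)
        # cycle-closing edges lie off the BFS tree
        tree_edges = set()
        for nb, pe in parent_edge.items():
            if pe is not None:
                cur, key, _ = pe
                tree_edges.add((min(cur, nb), max(cur, nb), key))
        for a, b, key, data in list(G.edges(nodes, keys=True, data=True)):
            if (min(a, b), max(a, b), key) not in tree_edges:
                if not break_cycles:
                    continue
                G.remove_edge(a, b, key)
                removed.append(data["section"])
        # post-order accumulation of upstream lengths
        max_up = {n: 0.0 for n in nodes}
        tot_up = {n: 0.0 for n in nodes}
        for nb in reversed(order_nodes):
            if parent_edge[nb] is None:
                continue
            cur, _, sid = parent_edge[nb]
            sec = skel.sections[sid]
            max_up[cur] = max(max_up[cur], sec.length + max_up[nb])
            tot_up[cur] += sec.length + tot_up[nb]
        for n in nodes:
            G.nodes[n]["max_upstream"] = max_up[n]
            G.nodes[n]["total_upstream"] = tot_up[n]
            deg = G.degree(n)
            if n == out_node:
                G.nodes[n]["kind"] = "outlet"
            elif deg == 1:
                G.nodes[n]["kind"] = "head"
            else:
                G.nodes[n]["kind"] = "junction"
    if removed:
        skel.n_cycle_edges_removed = len(removed)
        _compact_sections(skel)
    for sec in skel.sections:
        up = sec.end_node
        rem = sec.length - sec.point_arc
        sec.upstream_max_length = rem + G.nodes[up]["max_upstream"]
        sec.upstream_total_length = rem + G.nodes[up]["total_upstream"]
    return skel


def fill_depressions(elevation: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Priority-flood depression filling with an epsilon slope.

    Floods inward from all raster-boundary cells in increasing elevation
    order; every flooded cell is raised to at least its flood parent plus
    ``eps``, which removes pits and flats so that every interior cell of
    the result has a strictly lower neighbor (D8 routing is well defined).
    """
    elev = np.asarray(elevation, dtype=float)
    n_r, n_c = elev.shape
    filled = np.full_like(elev, np.inf)
    closed = np.zeros_like(elev, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for r in range(n_r):
        for c in (0, n_c - 1):
            heapq.heappush(heap, (elev[r, c], counter, r, c))
            counter += 1
    for c in range(1, n_c - 1):
        for r in (0, n_r - 1):
            heapq.heappush(heap, (elev[r, c], counter, r, c))
            counter += 1
    while heap:
        z, _, r, c = heapq.heappop(heap)
        if closed[r, c]:
            continue
        closed[r, c] = True
        filled[r, c] = z
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_r and 0 <= cc < n_c and not closed[rr, cc]:
                zz = max(elev[rr, cc], z + eps)
                heapq.heappush(heap, (zz, counter, rr, cc))
                counter += 1
    return filled


def flow_accumulation(dtm: DTMRaster) -> np.ndarray:
    """D8 flow accumulation (m^2) after depression filling.

    Each cell drains to its steepest-descent 8-neighbor (drop divided by
    distance; orthogonal neighbors checked before diagonals on ties);
    accumulated contributing area includes the cell itself. Boundary cells
    without a lower neighbor drain out of the raster.
    """
    filled = fill_depressions(dtm.elevation)
    n_r, n_c = filled.shape
    pad = np.pad(filled, 1, constant_values=np.inf)
    best_grad = np.full((n_r, n_c), 0.0)
    recv = np.full((n_r, n_c), -1, dtype=np.int64)
    idx = np.arange(n_r * n_c).reshape(n_r, n_c)
    for dr, dc in _NEIGHBORS8:
        nb = pad[1 + dr:1 + dr + n_r, 1 + dc:1 + dc + n_c]
        dist = math.hypot(dr, dc)
        grad = (filled - nb) / dist
        better = grad > best_grad
        best_grad = np.where(better, grad, best_grad)
        shifted = np.roll(np.roll(idx, -dr, axis=0), -dc, axis=1)
        recv = np.where(better, shifted, recv)
    # cells whose best neighbor lies outside the raster drain away: their
    # padded neighbor is +inf so grad is -inf there and recv stays -1 or a
    # valid in-raster cell.
    acc = np.ones(n_r * n_c)
    order = np.argsort(filled.ravel(), kind="stable")[::-1]
    recv_flat = recv.ravel()
    for i in order:
        r = recv_flat[i]
        if r >= 0:
            acc[r] += acc[i]
    return acc.reshape(n_r, n_c) * dtm.pixel_size ** 2


def watershed_areas(dtm: DTMRaster, skel: Skeleton) -> Skeleton:
    """Attach the D8 contributing area (m^2) to every skeleton point.

    The area at a point is the *total* upstream accumulated area of the
    nearest raster cell, so it is non-decreasing downstream along a flow
    path and the outlet point carries the full contributing area.
    """
    if dtm.shape != skel.shape:
        raise ValueError("DTM and skeleton are not aligned")
    acc = flow_accumulation(dtm)
    for sec in skel.sections:
        rr = np.clip(np.round(sec.points[:, 0]).astype(int), 0,
                     dtm.shape[0] - 1)
        cc = np.clip(np.round(sec.points[:, 1]).astype(int), 0,
                     dtm.shape[1] - 1)
        sec.area = acc[rr, cc]
    return skel


def hack_order(skel: Skeleton) -> Skeleton:
    """Assign Hack stream orders and subbasin identifiers.

    Walking upstream from each outlet, the tributary with the greater
    maximum upstream length continues the parent stream's order; every
    other tributary starts a new stream of order+1. Ties break on greater
    watershed area at the junction, then on lower section id. Each maximal
    same-order head-to-junction path is one stream/subbasin with a unique
    identifier; outlet streams have order 1.
    """
    G = skel.graph
    if not skel.outlets:
        raise ValueError("skeleton is not oriented: call orient_skeleton")
    try:
        nx.find_cycle(G)
        raise ValueError("skeleton graph contains a cycle; Hack ordering "
                         "is defined on trees")
    except nx.NetworkXNoCycle:
        pass
    next_basin = 1
    for out_node in skel.outlets:
        upstream: dict[int, list[Section]] = {}
        for sec in skel.sections:
            upstream.setdefault(sec.start_node, []).append(sec)

        def rank(sec: Section) -> tuple:
            area = float(sec.area[0]) if sec.area is not None else 0.0
            return (sec.length + G.nodes[sec.end_node]["max_upstream"],
                    area, -sec.id)

        stack: list[tuple[int, int, int | None]] = [(out_node, 1, None)]
        while stack:
            node, order, basin = stack.pop()
            children = upstream.get(node, [])
            if not children:
                continue
            children = sorted(children, key=rank, reverse=True)
            for i, sec in enumerate(children):
                if i == 0:
                    if basin is None:       # outlet: start the main stream
                        sec.order = order
                        sec.subbasin = next_basin
                        next_basin += 1
                    else:                   # dominant tributary continues
                        sec.order, sec.subbasin = order, basin
                else:                       # side tributary: finer order
                    sec.order = order + 1
                    sec.subbasin = next_basin
                    next_basin += 1
                stack.append((sec.end_node, sec.order, sec.subbasin))
    return skel


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def stream_counts(skel: Skeleton) -> np.ndarray:
    """Number of streams (distinct subbasins) per Hack order, index 0 being
    order 1. Empty array if no section is ordered."""
    pairs = {(s.order, s.subbasin) for s in skel.sections
             if s.order is not None}
    if not pairs:
        return np.array([], dtype=int)
    max_order = max(o for o, _ in pairs)
    counts = np.zeros(max_order, dtype=int)
    for o, _ in pairs:
        counts[o - 1] += 1
    return counts


def bifurcation_ratios(counts) -> np.ndarray:
    """Hack bifurcation ratios r_i = n_{i+1} / n_i for consecutive orders.

    With Hack ordering, higher order means finer scale, so r_i measures how
    many next-finer streams each stream of order i spawns on average.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        return np.array([])
    return counts[1:] / counts[:-1]


def hortonian_drainage_density(skel: Skeleton, basin_area: float) -> float:
    """Total network length divided by the total watershed area (m^-1)."""
    if basin_area <= 0:
        raise ValueError(f"basin_area must be > 0, got {basin_area}")
    return skel.total_length / basin_area


def exceedance(samples) -> tuple[np.ndarray, np.ndarray]:
    """Empirical exceedance (survival) curve.

    Returns the sorted unique sample values t and P(X > t) evaluated just
    past each value (right-continuous), decreasing from below 1 toward 0.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    vals, counts = np.unique(x, return_counts=True)
    probs = 1.0 - np.cumsum(counts) / x.size
    return vals, probs


def exceedance_at(samples, thresholds) -> np.ndarray:
    """P(X > threshold) for arbitrary thresholds."""
    x = np.sort(np.asarray(samples, dtype=float))
    t = np.atleast_1d(np.asarray(thresholds, dtype=float))
    return 1.0 - np.searchsorted(x, t, side="right") / x.size


def ks_similarity(sample_a, sample_b,
                  method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov similarity.

    Returns (1 - KS, p-value): the headline similarity in [0, 1] is one
    minus the KS statistic (the supremum ECDF gap over the pooled support).
    ``method`` is passed to the underlying test ("auto", "exact" or
    "asymp"); the p-value is reported alongside for reference.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(a, b, method=method)
    return 1.0 - float(res.statistic), float(res.pvalue)


def pattern_correlation(S: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation between the bed-elevation and vegetation
    patterns over all cells; stronger positive correlation indicates
    stronger vegetative control on the morphology."""
    S = np.asarray(S, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    if S.shape != B.shape:
        raise ValueError("fields must have equal shapes")
    if S.std() == 0 or B.std() == 0:
        raise ValueError("pattern correlation undefined for a constant field")
    return float(stats.pearsonr(S, B).statistic)


@dataclass
class NetworkStats:
    """Summary geometry statistics of one channel network."""

    stream_counts: np.ndarray
    bifurcation_ratios: np.ndarray
    drainage_density: float
    total_length: float
    basin_area: float
    area_samples: np.ndarray
    upl_samples: np.ndarray
    max_order: int

    def exceedance_area(self):
        return exceedance(self.area_samples)

    def exceedance_upl(self):
        return exceedance(self.upl_samples)


_EMPTY_STATS = dict(stream_counts=np.array([], dtype=int),
                    bifurcation_ratios=np.array([]),
                    drainage_density=0.0, total_length=0.0,
                    area_samples=np.array([]), upl_samples=np.array([]),
                    max_order=0)


def network_statistics(skel: Skeleton, mask: ChannelMask,
                       basin_area: float) -> NetworkStats:
    """Assemble the statistics of an ordered skeleton: per-order stream
    counts and bifurcation ratios, Hortonian drainage density, watershed
    areas at every equidistant skeleton point and unchanneled path lengths
    at every unchanneled cell."""
    counts = stream_counts(skel)
    upl = unchanneled_path_length(mask)
    return NetworkStats(
        stream_counts=counts,
        bifurcation_ratios=bifurcation_ratios(counts),
        drainage_density=hortonian_drainage_density(skel, basin_area),
        total_length=skel.total_length,
        basin_area=basin_area,
        area_samples=skel.points_with("area"),
        upl_samples=upl[~mask.mask],
        max_order=int(counts.size),
    )


def analyze_dtm(dtm: DTMRaster, window_radius: float, depth_threshold: float,
                *, prune_factor: float = 2.0, spacing: float = 0.5,
                outlet: str = "open-edge", basin_area: float | None = None,
                ) -> tuple[ChannelMask, Skeleton | None, NetworkStats]:
    """End-to-end extraction: detect -> skeletonize -> orient -> watershed
    areas -> Hack orders -> statistics.

    When no channels are detected (over-smoothed terrain) the skeleton is
    None and the statistics are all-zero/empty, mirroring terrain whose
    network cannot be extracted.
    """
    if basin_area is None:
        basin_area = dtm.area
    mask = detect_channels(dtm, window_radius, depth_threshold)
    if not mask.mask.any():
        return mask, None, NetworkStats(basin_area=basin_area, **_EMPTY_STATS)
    skel = skeletonize(mask, prune_factor=prune_factor, spacing=spacing)
    if not skel.sections:
        return mask, None, NetworkStats(basin_area=basin_area, **_EMPTY_STATS)
    orient_skeleton(skel, dtm=dtm, outlet=outlet)
    watershed_areas(dtm, skel)
    hack_order(skel)
    return mask, skel, network_statistics(skel, mask, basin_area)


def skeleton_from_sections(node_rc: dict[int, tuple[int, int]],
                           section_paths: list[tuple[int, int, np.ndarray]],
                           pixel_size: float, shape: tuple[int, int],
                           spacing: float = 0.5) -> Skeleton:
    """Build a Skeleton directly from known topology (bypassing raster
    detection), e.g. from fixture ground truth: ``section_paths`` holds
    (node_a, node_b, pixel_path) triples."""
    G = nx.MultiGraph()
    for nid, rc in node_rc.items():
        G.add_node(nid, rc=tuple(rc))
    sections = []
    for a, b, path in section_paths:
        arr = np.asarray(path)
        sec = Section(id=len(sections), start_node=a, end_node=b,
                      pixels=arr, length=_path_length(arr, pixel_size))
        sec.points, sec.point_arc = _resample(arr, pixel_size, spacing)
        G.add_edge(a, b, section=sec.id)
        sections.append(sec)
    return Skeleton(graph=G, sections=sections, pixel_size=pixel_size,
                    shape=shape, spacing=spacing)
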