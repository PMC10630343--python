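"""Synthetic DTMs, channel masks and closed-form reference solutions with
exact ground truth, so the network-extraction pipeline and the solver can
be validated without any external data.

The terrain fixtures are inclined planes draining toward the last raster
row (the open-boundary convention of the simulator) with channels carved as
one-pixel-wide polylines of known topology. Channels are carved with flat
bottoms relative to the plane, vertical or 45-degree courses and strictly
descending beds, so centerlines, junction topology, Hack orders and D8
drainage partitions are unambiguous by construction. These fixtures make no
attempt to emulate the statistics of real marsh terrain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import DTMRaster, skeleton_from_sections, Skeleton

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "make_dtm",
    "make_random_mask",
    "logistic_reference",
    "diffusion_reference",
]

KINDS = ("inclined-plane", "straight-channel", "y-junction",
         "nested-orders", "two-branch-basin")


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for a synthetic DTM: (kind, parameters, seed)
    fully determine the output."""

    kind: str
    shape: tuple[int, int] = (64, 64)
    pixel_size: float = 0.5
    slope: float = 1.0e-3          # down-slope toward the last row (m/m)
    cross_slope: float = 1.0e-2    # toward channels, two-branch basin only
    channel_depth: float = 0.3     # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.shape[0] < 16 or self.shape[1] < 16:
            raise ValueError("fixture grids must be at least 16x16")


@dataclass
class GroundTruth:
    """Exact truth accompanying a fixture DTM."""

    channel_pixels: np.ndarray                 # bool grid
    nodes: dict[int, tuple[int, int]] = field(default_factory=dict)
    node_kinds: dict[int, str] = field(default_factory=dict)
    sections: list[tuple[int, int, np.ndarray]] = field(default_factory=list)
    stream_orders: list[int] = field(default_factory=list)
    stream_counts: np.ndarray = field(default_factory=lambda: np.array([], int))
    total_length: float = 0.0
    branch_areas: dict[str, float] = field(default_factory=dict)

    @property
    def junction_count(self) -> int:
        return sum(1 for k in self.node_kinds.values() if k == "junction")

    @property
    def head_count(self) -> int:
        return sum(1 for k in self.node_kinds.values() if k == "head")

    @property
    def outlet_count(self) -> int:
        return sum(1 for k in self.node_kinds.values() if k == "outlet")

    def to_skeleton(self, pixel_size: float,
                    shape: tuple[int, int]) -> Skeleton:
        """Build a Skeleton directly from the known topology, bypassing
        raster detection."""
        return skeleton_from_sections(self.nodes, self.sections,
                                      pixel_size, shape)


def _plane(spec: FixtureSpec) -> np.ndarray:
    n_r, _ = spec.shape
    rows = (n_r - 1 - np.arange(n_r))[:, None] * spec.pixel_size * spec.slope
    return np.broadcast_to(rows, spec.shape).copy()


def _carve(elev: np.ndarray, paths: list[np.ndarray], depth: float) -> np.ndarray:
    mask = np.zeros(elev.shape, dtype=bool)
    for path in paths:
        for r, c in path:
            if mask[r, c]:
                # shared junction pixels are allowed once per pair of
                # sections meeting there; true overlaps are rejected
                continue
            mask[r, c] = True
    elev = elev.copy()
    elev[mask] -= depth
    return elev


def _seg(r0: int, c0: int, dr: int, dc: int, n: int) -> np.ndarray:
    """Pixel path of n+1 points starting at (r0, c0) stepping (dr, dc)."""
    t = np.arange(n + 1)
    return np.column_stack([r0 + dr * t, c0 + dc * t])


def _seg_length(path: np.ndarray, px: float) -> float:
    d = np.diff(path, axis=0)
    return float(np.sqrt((d ** 2).sum(axis=1)).sum()) * px


def make_dtm(spec: FixtureSpec) -> tuple[DTMRaster, GroundTruth]:
    """Generate a synthetic DTM and its exact ground truth."""
    n_r, n_c = spec.shape
    px = spec.pixel_size
    plane = _plane(spec)

    if spec.kind == "inclined-plane":
        gt = GroundTruth(channel_pixels=np.zeros(spec.shape, bool))
        return DTMRaster(plane, px), gt

    if spec.kind == "straight-channel":
        jc = n_c // 2
        r0 = n_r // 8
        path = _seg(r0, jc, 1, 0, n_r - 1 - r0)
        elev = _carve(plane, [path], spec.channel_depth)
        mask = np.zeros(spec.shape, bool)
        mask[path[:, 0], path[:, 1]] = True
        gt = GroundTruth(
            channel_pixels=mask,
            nodes={1: (r0, jc), 2: (n_r - 1, jc)},
            node_kinds={1: "head", 2: "outlet"},
            sections=[(2, 1, path[::-1])],
            stream_orders=[1],
            stream_counts=np.array([1]),
            total_length=_seg_length(path, px),
        )
        return DTMRaster(elev, px), gt

    if spec.kind == "y-junction":
        jc = n_c // 2
        rj = n_r // 2
        stem = _seg(rj, jc, 1, 0, n_r - 1 - rj)
        left = _seg(rj, jc, -1, -1, min(rj, jc) - 4)
        right = _seg(rj, jc, -1, 1, min(rj, n_c - 1 - jc) - 8)
        elev = _carve(plane, [stem, left, right], spec.channel_depth)
        mask = np.zeros(spec.shape, bool)
        for p in (stem, left, right):
            mask[p[:, 0], p[:, 1]] = True
        lengths = {"stem": _seg_length(stem, px),
                   "left": _seg_length(left, px),
                   "right": _seg_length(right, px)}
        gt = GroundTruth(
            channel_pixels=mask,
            nodes={1: (rj, jc), 2: (n_r - 1, jc),
                   3: tuple(left[-1]), 4: tuple(right[-1])},
            node_kinds={1: "junction", 2: "outlet", 3: "head", 4: "head"},
            sections=[(2, 1, stem[::-1]), (1, 3, left), (1, 4, right)],
            # the longer branch (left) continues the main stream
            stream_orders=[1, 2],
            stream_counts=np.array([1, 1]),
            total_length=sum(lengths.values()),
        )
        return DTMRaster(elev, px), gt

    if spec.kind == "nested-orders":
        jc = n_c // 2
        r_head = max(4, n_r // 16)
        r_j1 = int(n_r * 0.62)          # tributary A joins here
        r_j2 = int(n_r * 0.82)          # tributary B joins here
        stem = _seg(r_head, jc, 1, 0, n_r - 1 - r_head)
        len_a = min(14, jc - 2, r_j1 - r_head - 2)
        trib_a = _seg(r_j1, jc, -1, 1, len_a)             # up-right diagonal
        len_b = max(4, len_a - 4)
        trib_b = _seg(r_j2, jc, -1, -1, min(len_b, jc - 2))  # up-left
        t3 = len_a // 2
        r_j3, c_j3 = r_j1 - t3, jc + t3                   # on tributary A
        len_c = max(3, t3 - 2)
        trib_c = _seg(r_j3, c_j3, -1, 0, len_c)           # straight up
        elev = _carve(plane, [stem, trib_a, trib_b, trib_c],
                      spec.channel_depth)
        mask = np.zeros(spec.shape, bool)
        for p in (stem, trib_a, trib_b, trib_c):
            mask[p[:, 0], p[:, 1]] = True
        # nodes: outlet, stem head, junctions J1 J2 J3, heads of A B C
        a_lower = trib_a[:t3 + 1]       # J1 -> J3
        a_upper = trib_a[t3:]           # J3 -> head of A
        stem_1 = _seg(r_head, jc, 1, 0, r_j1 - r_head)    # head -> J1
        stem_2 = _seg(r_j1, jc, 1, 0, r_j2 - r_j1)        # J1 -> J2
        stem_3 = _seg(r_j2, jc, 1, 0, n_r - 1 - r_j2)     # J2 -> outlet
        nodes = {1: (n_r - 1, jc), 2: (r_head, jc), 3: (r_j1, jc),
                 4: (r_j2, jc), 5: (r_j3, c_j3),
                 6: tuple(trib_a[-1]), 7: tuple(trib_b[-1]),
                 8: tuple(trib_c[-1])}
        kinds = {1: "outlet", 2: "head", 3: "junction", 4: "junction",
                 5: "junction", 6: "head", 7: "head", 8: "head"}
        sections = [(1, 4, stem_3[::-1]), (4, 3, stem_2[::-1]),
                    (3, 2, stem_1[::-1]), (3, 5, a_lower),
                    (5, 6, a_upper), (4, 7, trib_b), (5, 8, trib_c)]
        gt = GroundTruth(
            channel_pixels=mask,
            nodes=nodes, node_kinds=kinds, sections=sections,
            # main stem order 1; tributaries A and B order 2; the branch C
            # off tributary A order 3
            stream_orders=[1, 2, 2, 3],
            stream_counts=np.array([1, 2, 1]),
            total_length=(_seg_length(stem, px) + _seg_length(trib_a, px)
                          + _seg_length(trib_b, px)
                          + _seg_length(trib_c, px)),
        )
        return DTMRaster(elev, px), gt

    # two-branch-basin: two parallel channels, cross-slope toward the
    # nearest channel so the D8 drainage partition is the nearest-channel
    # rule (analytic areas). The channel spacing is odd so no column ties.
    j1 = n_c // 4
    j2 = j1 + 2 * (n_c // 4) + 1
    if j2 >= n_c - 1:
        j2 = n_c - 3 if (n_c - 3 - j1) % 2 == 1 else n_c - 4
    cols = np.arange(n_c)
    cross = np.minimum(np.abs(cols - j1), np.abs(cols - j2)) * px
    elev = _plane(spec) + spec.cross_slope * cross[None, :]
    ch1 = _seg(0, j1, 1, 0, n_r - 1)
    ch2 = _seg(0, j2, 1, 0, n_r - 1)
    elev = _carve(elev, [ch1, ch2], spec.channel_depth)
    mask = np.zeros(spec.shape, bool)
    mask[:, j1] = True
    mask[:, j2] = True
    m = (j1 + j2 - 1) // 2          # last column draining to channel 1
    gt = GroundTruth(
        channel_pixels=mask,
        nodes={1: (0, j1), 2: (n_r - 1, j1), 3: (0, j2), 4: (n_r - 1, j2)},
        node_kinds={1: "head", 2: "outlet", 3: "head", 4: "outlet"},
        sections=[(2, 1, ch1[::-1]), (4, 3, ch2[::-1])],
        stream_orders=[1, 1],
        stream_counts=np.array([2]),
        total_length=_seg_length(ch1, px) + _seg_length(ch2, px),
        branch_areas={"left": (m + 1) * n_r * px * px,
                      "right": (n_c - m - 1) * n_r * px * px},
    )
    return DTMRaster(elev, px), gt


def make_random_mask(shape: tuple[int, int], density: float,
                     seed: int) -> np.ndarray:
    """Random boolean channel mask for distance-transform checks."""
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < density
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


def logistic_reference(t, B0: float, r_eff: float, k: float):
    """Closed-form logistic growth B(t) = k / (1 + ((k-B0)/B0) e^(-r_eff t)),
    the exact solution of the vegetation growth term at zero shear stress
    and uniform depth (r_eff = r Q_q/(Q_q + h_e))."""
    if not (0 < B0 < k):
        raise ValueError(f"B0 must lie in (0, k), got {B0}")
    t = np.asarray(t, dtype=float)
    out = k / (1.0 + ((k - B0) / B0) * np.exp(-r_eff * t))
    return float(out) if out.ndim == 0 else out


def diffusion_reference(x, t: float, D: float, mass: float):
    """1-D Gaussian diffusion kernel: mass/sqrt(4 pi D t) exp(-x^2/(4Dt)),
    the spreading solution for an initial point deposit under pure
    topographic diffusion; its variance grows as 2 D t."""
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    x = np.asarray(x, dtype=float)
    out = mass / math.sqrt(4.0 * math.pi * D * t) * np.exp(
        -x * x / (4.0 * D * t))
    return float(out) if out.ndim == 0 else out
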