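"""Neighborhood segmentation and histogram extraction.

The neighborhood of an element is a disc centred on it, divided by radial
lines and concentric circles into *grids*, each addressed by a
``(shell, sector)`` pair. By default 8 sectors x 3 shells = 24 grids: shells
are numbered 0..2 from the inside out, sectors 0..7 counterclockwise from the
+x axis. The local arrangement of neighbors is summarised as one count vector
("neighborhood histogram") per species: bin ``shell * n_sectors + sector``
holds the number of neighbors of that species falling in the grid.

The innermost circle radius r0 defaults to the shortest pairwise distance in
the sample pattern; shells are equally spaced at r0, 2*r0, ..., so the outer
radius is ``n_shells * r0``. All radial intervals are half-open
``[inner, outer)`` and sectors are half-open ``[k*360/n, (k+1)*360/n)``
degrees, which makes the grid assignment a true partition of the punctured
disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.spatial import cKDTree, Delaunay
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .pattern import Element, VectorPattern

__all__ = [
    "NeighborhoodGeometry",
    "GridIndex",
    "NeighborhoodHistogramSet",
    "estimate_base_radius",
    "connectivity_radius",
    "assign_to_grid",
    "assign_bins",
    "bin_index",
    "representative_point",
    "representative_offsets",
    "compute_histograms",
    "neighbor_pairs",
    "sample_histogram_table",
]


@dataclass(frozen=True)
class GridIndex:
    """Address of one neighborhood grid: radial shell and angular sector."""

    shell: int
    sector: int


@dataclass(frozen=True)
class NeighborhoodGeometry:
    """Disc segmentation: ``n_shells`` rings of width ``r0``, ``n_sectors`` wedges."""

    r0: float
    n_sectors: int = 8
    n_shells: int = 3

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be strictly positive")
        if self.n_sectors < 1 or self.n_shells < 1:
            raise ValueError("n_sectors and n_shells must be >= 1")

    @property
    def shell_radii(self) -> np.ndarray:
        """Outer radius of each shell: r0, 2*r0, ..., n_shells*r0."""
        return self.r0 * np.arange(1, self.n_shells + 1, dtype=float)

    @property
    def outer_radius(self) -> float:
        return self.n_shells * self.r0

    @property
    def n_bins(self) -> int:
        return self.n_shells * self.n_sectors

    @property
    def sector_width(self) -> float:
        """Angular width of one sector in radians."""
        return 2.0 * np.pi / self.n_sectors


@dataclass
class NeighborhoodHistogramSet:
    """Per-species 24-bin neighbor counts around one element.

    ``mask[b]`` is True when bin ``b`` is *determined*, i.e. its count can be
    trusted. Histograms computed on a sample pattern are fully determined;
    during synthesis the mask marks which grids already lie in previously
    extended neighborhoods.
    """

    counts: Dict[int, np.ndarray]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n_bins = {len(v) for v in self.counts.values()}
        if len(n_bins) > 1:
            raise ValueError("all count vectors must share one bin count")
        nb = n_bins.pop() if n_bins else 0
        if self.mask is None:
            self.mask = np.ones(nb, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if nb and len(self.mask) != nb:
            raise ValueError("mask length must equal the bin count")

    @property
    def type_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.counts))

    def stacked(self, type_order) -> np.ndarray:
        """Counts as an array of shape (len(type_order), n_bins)."""
        return np.stack(
            [
                np.asarray(
                    self.counts.get(t, np.zeros(len(self.mask))), dtype=float
                )
                for t in type_order
            ]
        )


def estimate_base_radius(pattern: VectorPattern) -> float:
    """Shortest pairwise distance between elements, the default r0.

    Raises on patterns with fewer than two elements and on coincident
    positions (which would make the innermost circle empty of meaning).
    """
    if pattern.n < 2:
        raise ValueError("pattern too small: need at least 2 elements")
    xy = pattern.xy
    tree = cKDTree(xy)
    dist, _ = tree.query(xy, k=2)
    d_min = float(dist[:, 1].min())
    if d_min == 0.0:
        raise ValueError("coincident elements: minimum pairwise distance is 0")
    return d_min


def connectivity_radius(pattern: VectorPattern) -> float:
    """Largest edge of the Euclidean minimum spanning tree of the elements.

    Any disc radius above this value guarantees that every element can be
    reached from any other by hops between overlapping neighborhoods — the
    scale a growth process must see to cross the widest gap in the pattern.
    """
    if pattern.n < 2:
        raise ValueError("pattern too small: need at least 2 elements")
    xy = pattern.xy
    if pattern.n == 2:
        return float(np.hypot(*(xy[1] - xy[0])))
    try:
        tri = Delaunay(xy)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                edges.add((min(i, j), max(i, j)))
        ii, jj = np.array(sorted(edges)).T
    except Exception:
        # degenerate (collinear) input: fall back to the complete graph
        ii, jj = np.triu_indices(pattern.n, k=1)
    w = np.hypot(*(xy[ii] - xy[jj]).T)
    graph = coo_matrix((w, (ii, jj)), shape=(pattern.n, pattern.n))
    mst = minimum_spanning_tree(graph)
    return float(mst.data.max())


def assign_bins(dx, dy, geom: NeighborhoodGeometry) -> np.ndarray:
    """Vectorized grid assignment for offsets from the centre element.

    Returns the flattened bin index per offset, or -1 when the offset lies at
    or beyond the outer radius. Zero offsets are the caller's responsibility.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    r = np.hypot(dx, dy)
    shell = np.searchsorted(geom.shell_radii, r, side="right")
    angle = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    sector = np.floor(angle / geom.sector_width).astype(np.int64)
    sector = np.minimum(sector, geom.n_sectors - 1)  # guard angle == 2*pi
    bins = shell * geom.n_sectors + sector
    return np.where(shell >= geom.n_shells, -1, bins)


def assign_to_grid(
    center, point, geom: NeighborhoodGeometry
) -> Optional[GridIndex]:
    """Grid containing ``point`` as seen from ``center``, or None if outside.

    The shell is the index of the smallest concentric circle whose radius
    exceeds the distance; the sector counts counterclockwise from the +x axis.
    """
    cx, cy = float(center[0]), float(center[1])
    px, py = float(point[0]), float(point[1])
    if px == cx and py == cy:
        raise ValueError("self-assignment: point coincides with center")
    b = int(assign_bins(px - cx, py - cy, geom))
    if b < 0:
        return None
    return GridIndex(shell=b // geom.n_sectors, sector=b % geom.n_sectors)


def bin_index(g: GridIndex, geom: NeighborhoodGeometry) -> int:
    """Flattened histogram bin: ``shell * n_sectors + sector``."""
    if not (0 <= g.shell < geom.n_shells and 0 <= g.sector < geom.n_sectors):
        raise ValueError(f"grid index {g} out of range for {geom}")
    return g.shell * geom.n_sectors + g.sector


def representative_point(
    g: GridIndex, geom: NeighborhoodGeometry, center=(0.0, 0.0)
) -> tuple[float, float]:
    """Polar midpoint of a grid: mid-shell radius at the sector's mid-angle."""
    bin_index(g, geom)  # validate
    inner = g.shell * geom.r0
    outer = (g.shell + 1) * geom.r0
    radius = 0.5 * (inner + outer)
    angle = (g.sector + 0.5) * geom.sector_width
    return (
        float(center[0] + radius * np.cos(angle)),
        float(center[1] + radius * np.sin(angle)),
    )


def representative_offsets(geom: NeighborhoodGeometry) -> np.ndarray:
    """Representative points of all grids as offsets from the centre, (n_bins, 2)."""
    shells, sectors = np.divmod(np.arange(geom.n_bins), geom.n_sectors)
    radius = (shells + 0.5) * geom.r0
    angle = (sectors + 0.5) * geom.sector_width
    return np.column_stack((radius * np.cos(angle), radius * np.sin(angle)))


def compute_histograms(
    pattern: VectorPattern,
    element: Element,
    geom: NeighborhoodGeometry,
    type_order=None,
) -> NeighborhoodHistogramSet:
    """Per-species neighbor counts around ``element`` within the outer radius.

    The element itself is excluded; neighbors exactly at the outer radius are
    excluded (half-open shells). Sample-side histograms are fully determined,
    so the mask is all True.
    """
    if type_order is None:
        type_order = pattern.type_ids
    xy = pattern.xy
    dx = xy[:, 0] - element.x
    dy = xy[:, 1] - element.y
    not_self = ~((dx == 0.0) & (dy == 0.0) & (pattern.ids == element.id))
    bins = np.full(pattern.n, -1, dtype=np.int64)
    nz = not_self & ((dx != 0.0) | (dy != 0.0))
    bins[nz] = assign_bins(dx[nz], dy[nz], geom)
    counts: Dict[int, np.ndarray] = {}
    types = pattern.type_id_array
    for t in type_order:
        sel = (types == t) & (bins >= 0)
        counts[int(t)] = np.bincount(
            bins[sel], minlength=geom.n_bins
        ).astype(np.int64)
    return NeighborhoodHistogramSet(
        counts=counts, mask=np.ones(geom.n_bins, dtype=bool)
    )


def neighbor_pairs(
    pattern: VectorPattern,
    radius: float,
    periodic: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Unordered element pairs closer than ``radius``, with displacements.

    Returns ``(pairs, offsets)`` where ``pairs`` has shape (m, 2) of row
    indices and ``offsets[k] = position(pairs[k, 1]) - position(pairs[k, 0])``.
    With ``periodic=True`` the pattern's region is treated as a torus
    (minimum-image displacements), so border elements get full, untruncated
    neighborhoods; this requires ``radius`` below half the shorter side.
    """
    xy = pattern.xy
    if not periodic:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        offsets = xy[pairs[:, 1]] - xy[pairs[:, 0]] if len(pairs) else np.empty((0, 2))
        return pairs, offsets
    region = pattern.region
    box = np.array([region.width, region.height])
    if radius >= 0.5 * box.min():
        raise ValueError(
            "periodic neighborhoods need a radius below half the shorter "
            f"region side ({0.5 * box.min():.4g})"
        )
    q = np.mod(xy - (region.x_min, region.y_min), box)
    tree = cKDTree(q, boxsize=box)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        return pairs, np.empty((0, 2))
    d = q[pairs[:, 1]] - q[pairs[:, 0]]
    d -= box * np.round(d / box)  # minimum image
    return pairs, d


def sample_histogram_table(
    pattern: VectorPattern,
    geom: NeighborhoodGeometry,
    type_order=None,
    periodic: bool = False,
) -> np.ndarray:
    """Histograms of every element, shape (n, n_types, n_bins), float.

    One pass with a KD-tree; used to index the sample once before synthesis.
    ``periodic`` computes neighborhoods on the torus (see
    :func:`neighbor_pairs`).
    """
    if type_order is None:
        type_order = pattern.type_ids
    n, nb = pattern.n, geom.n_bins
    out = np.zeros((n, len(type_order), nb), dtype=float)
    if n == 0:
        return out
    t_pos = np.zeros(int(max(type_order)) + 1, dtype=np.int64)
    for k, t in enumerate(type_order):
        t_pos[int(t)] = k
    types = pattern.type_id_array
    pairs, offsets = neighbor_pairs(pattern, geom.outer_radius, periodic)
    if len(pairs) == 0:
        return out
    for i, j, sign in ((0, 1, 1.0), (1, 0, -1.0)):
        ci, cj = pairs[:, i], pairs[:, j]
        bins = assign_bins(sign * offsets[:, 0], sign * offsets[:, 1], geom)
        ok = bins >= 0
        np.add.at(out, (ci[ok], t_pos[types[cj[ok]]], bins[ok]), 1.0)
    return out
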