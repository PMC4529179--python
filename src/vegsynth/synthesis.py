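"""The pattern-growth loop: initialization, extension, termination.

Synthesis grows a large pattern from a small sample by Markov-random-field
style neighborhood matching on vector elements:

1. A randomly chosen sample element is placed at the centre of the target
   region and its neighborhood is copied verbatim (the *initial pattern*).
2. Repeatedly, the unextended element nearest the centre (the *extending
   element*) is selected. The grids of its neighborhood disc that lie inside
   previously extended discs are *determined*; their counts are trustworthy.
3. The sample element of the same species whose (fully determined) histogram
   set best matches the extending element's determined bins is found, and its
   neighbors are copied around the extending element — but only into
   territory not already covered by an extended disc, which the extension
   replenishes. A copy is also dropped when it lands closer than a conflict
   distance to an existing element, or beyond the growth margin around the
   target region.
4. The loop stops when every element inside the target region has been
   extended; the final pattern is clipped to the region.

Neighborhood radius policy: the shell width defaults to the sample's shortest
pairwise distance (so the innermost circle can hold at most one neighbor),
but the outer radius is floored at ``connectivity_factor`` times the largest
Euclidean-MST edge of the sample. Growth advances at most one outer radius
per extension, so the disc must be able to span the widest gap between
neighboring elements; for designed or regularly spaced stands the floor is
inactive and the behavior is exactly the minimum-distance rule.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from .geometry import (
    NeighborhoodGeometry,
    assign_bins,
    connectivity_radius,
    estimate_base_radius,
    neighbor_pairs,
    representative_offsets,
)
from .matching import (
    MatchWeights,
    SampleMatcher,
    SimilarityMatrix,
    build_similarity_matrix,
)
from .pattern import Element, Region, VectorPattern

__all__ = [
    "SynthesisParams",
    "SynthesisState",
    "initialize_synthesis",
    "select_extending_element",
    "determine_known_grids",
    "extend_once",
    "synthesize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthesisParams:
    """Tunable knobs of the growth process.

    sigma : smoothing strength of the similarity matrix (sane range 1-10).
    sector_mode : ``literal`` or ``circular`` sector distance.
    weights : per-species match weights; default uniform.
    conflict_radius_fraction : copies closer than this fraction of the
        sample's minimum pairwise distance to an existing element are dropped.
    r0 : shell width override; None estimates it from the sample.
    connectivity_factor : floor on the outer radius, in units of the sample's
        largest MST edge; 0 disables the floor. Ignored when r0 is given.
    periodic_sample : analyze the sample on a torus (minimum-image
        neighborhoods), so border elements carry full neighborhoods instead
        of truncated ones. Without it, sample-border truncation mimics the
        synthesis frontier's missing counts, wins matches at distance zero
        and starves the growth. Caps the outer radius below half the
        sample's shorter side.
    max_extensions : hard cap on the number of extensions (None = unlimited).
    seed : drives the initial element choice; everything else is
        deterministic.
    """

    sigma: float = 5.0
    sector_mode: str = "literal"
    weights: Optional[MatchWeights] = None
    conflict_radius_fraction: float = 0.5
    r0: Optional[float] = None
    connectivity_factor: float = 1.5
    periodic_sample: bool = True
    n_sectors: int = 8
    n_shells: int = 3
    max_extensions: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conflict_radius_fraction < 1.0:
            raise ValueError("conflict_radius_fraction must lie in (0, 1)")
        if not 1.0 <= self.sigma <= 10.0:
            warnings.warn(
                f"sigma={self.sigma} is outside the recommended range [1, 10]",
                stacklevel=2,
            )


class _SpatialHash:
    """Uniform-grid index over a growing set of points."""

    def __init__(self, cell: float) -> None:
        self.cell = float(cell)
        self._cells: Dict[tuple[int, int], List[int]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(np.floor(x / self.cell)), int(np.floor(y / self.cell)))

    def insert(self, idx: int, x: float, y: float) -> None:
        self._cells.setdefault(self._key(x, y), []).append(idx)

    def candidates(self, x: float, y: float, radius: float) -> List[int]:
        """Indices in cells overlapping the square around (x, y)."""
        span = int(np.ceil(radius / self.cell))
        ix, iy = self._key(x, y)
        out: List[int] = []
        for cx in range(ix - span, ix + span + 1):
            for cy in range(iy - span, iy + span + 1):
                got = self._cells.get((cx, cy))
                if got:
                    out.extend(got)
        return out


class _PointStore:
    """Append-only coordinate array with capacity doubling."""

    def __init__(self, capacity: int = 256) -> None:
        self._xy = np.empty((capacity, 2), dtype=float)
        self.n = 0

    def append(self, x: float, y: float) -> int:
        if self.n == len(self._xy):
            grown = np.empty((2 * len(self._xy), 2), dtype=float)
            grown[: self.n] = self._xy
            self._xy = grown
        self._xy[self.n] = (x, y)
        self.n += 1
        return self.n - 1

    @property
    def xy(self) -> np.ndarray:
        return self._xy[: self.n]


@dataclass
class SynthesisState:
    """The growing synthesis pattern plus every cache the loop needs."""

    sample: VectorPattern
    target_region: Region
    params: SynthesisParams
    geom: NeighborhoodGeometry
    A: SimilarityMatrix
    matcher: SampleMatcher
    rng_seed: int
    r0_min: float
    conflict_dist: float
    grow_region: Region
    center_id: int = 0
    # element storage
    points: _PointStore = field(default_factory=_PointStore)
    type_id_list: List[int] = field(default_factory=list)
    attr_list: List[tuple] = field(default_factory=list)  # (dbh, height, crown)
    extended_flags: List[bool] = field(default_factory=list)
    extended_ids: set = field(default_factory=set)
    n_extensions: int = 0
    # caches
    _heap: list = field(default_factory=list)
    _all_hash: _SpatialHash = None  # type: ignore[assignment]
    _ext_hash: _SpatialHash = None  # type: ignore[assignment]
    _conflict_hash: _SpatialHash = None  # type: ignore[assignment]
    _rep_offsets: np.ndarray = None  # type: ignore[assignment]
    _neighbors: list = None  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return self.points.n

    @property
    def center_element(self) -> Element:
        return self._element(self.center_id)

    def _element(self, idx: int) -> Element:
        x, y = self.points.xy[idx]
        dbh, height, crown = self.attr_list[idx]
        return Element(
            id=idx, x=float(x), y=float(y), type_id=self.type_id_list[idx],
            dbh=dbh, height=height, crown_width=crown,
        )

    @property
    def pattern(self) -> VectorPattern:
        """Snapshot of the current growth, over the inflated growth region."""
        return VectorPattern(
            [self._element(i) for i in range(self.n)], self.grow_region
        )

    # -- internal mutation -------------------------------------------------

    def _add_element(self, x, y, type_id, attrs) -> int:
        idx = self.points.append(float(x), float(y))
        self.type_id_list.append(int(type_id))
        self.attr_list.append(attrs)
        self.extended_flags.append(False)
        self._all_hash.insert(idx, x, y)
        self._conflict_hash.insert(idx, x, y)
        if self.target_region.contains(x, y):
            cx, cy = self.target_region.center
            heapq.heappush(self._heap, (float(np.hypot(x - cx, y - cy)), idx))
        return idx

    def _mark_extended(self, idx: int) -> None:
        self.extended_flags[idx] = True
        self.extended_ids.add(idx)
        x, y = self.points.xy[idx]
        self._ext_hash.insert(idx, x, y)

    def _near(self, hash_: _SpatialHash, x, y, radius) -> np.ndarray:
        """Indices of stored points strictly within ``radius`` of (x, y)."""
        cand = hash_.candidates(x, y, radius)
        if not cand:
            return np.empty(0, dtype=np.int64)
        idx = np.asarray(cand, dtype=np.int64)
        d = self.points.xy[idx] - (x, y)
        return idx[np.hypot(d[:, 0], d[:, 1]) < radius]


def _sample_neighbor_table(
    sample: VectorPattern, geom: NeighborhoodGeometry, periodic: bool = False
):
    """Per sample row: offsets, bins, types and attributes of its neighbors."""
    types = sample.type_id_array
    df = sample.df
    attrs = [
        (
            _nan_to_none(df["dbh"].iloc[i]) if "dbh" in df else None,
            _nan_to_none(df["height"].iloc[i]) if "height" in df else None,
            _nan_to_none(df["crown_width"].iloc[i]) if "crown_width" in df else None,
        )
        for i in range(sample.n)
    ]
    nbrs: list[list[tuple[int, float, float]]] = [[] for _ in range(sample.n)]
    pairs, offsets = neighbor_pairs(sample, geom.outer_radius, periodic)
    for k in range(len(pairs)):
        i, j = int(pairs[k, 0]), int(pairs[k, 1])
        dx, dy = float(offsets[k, 0]), float(offsets[k, 1])
        nbrs[i].append((j, dx, dy))
        nbrs[j].append((i, -dx, -dy))
    table = []
    for i in range(sample.n):
        entries = sorted(nbrs[i])
        offs = (
            np.array([(dx, dy) for _, dx, dy in entries])
            if entries
            else np.empty((0, 2))
        )
        bins = (
            assign_bins(offs[:, 0], offs[:, 1], geom)
            if entries
            else np.empty(0, dtype=np.int64)
        )
        keep = bins >= 0  # strict-inequality outer boundary
        table.append(
            (
                offs[keep],
                bins[keep],
                types[[j for j, _, _ in entries]][keep],
                [attrs[entries[k][0]] for k in np.flatnonzero(keep)],
            )
        )
    return table, attrs


def _nan_to_none(v):
    v = float(v)
    return None if np.isnan(v) else v


def initialize_synthesis(
    sample: VectorPattern, region, params: Optional[SynthesisParams] = None
) -> SynthesisState:
    """Place a random sample element and its neighborhood at the region centre."""
    params = params or SynthesisParams()
    region = Region.from_any(region)
    if sample.n == 0:
        raise ValueError("sample pattern is empty")

    if params.r0 is not None:
        r0_min = float(params.r0)
        outer = params.n_shells * r0_min
    else:
        r0_min = estimate_base_radius(sample)
        outer = params.n_shells * r0_min
        if params.connectivity_factor and sample.n >= 2:
            floor = params.connectivity_factor * connectivity_radius(sample)
            outer = max(outer, floor)
    if params.periodic_sample:
        # minimum-image neighborhoods need the disc inside half the sample
        half = 0.5 * min(sample.region.width, sample.region.height)
        if outer >= half:
            warnings.warn(
                f"neighborhood radius {outer:.4g} capped below half the "
                f"sample's shorter side ({half:.4g}) for periodic analysis",
                stacklevel=2,
            )
            outer = 0.999 * half
    r0_eff = outer / params.n_shells
    geom = NeighborhoodGeometry(
        r0=r0_eff, n_sectors=params.n_sectors, n_shells=params.n_shells
    )
    if min(region.width, region.height) < 2.0 * geom.outer_radius:
        raise ValueError(
            "region too small: each side must be at least twice the "
            f"neighborhood radius ({2 * geom.outer_radius:.4g})"
        )

    A = build_similarity_matrix(geom, sigma=params.sigma, mode=params.sector_mode)
    weights = params.weights or MatchWeights.uniform(sample.type_ids)
    matcher = SampleMatcher(
        sample, geom, A, weights, periodic=params.periodic_sample
    )
    neighbor_table, _ = _sample_neighbor_table(
        sample, geom, periodic=params.periodic_sample
    )

    state = SynthesisState(
        sample=sample,
        target_region=region,
        params=params,
        geom=geom,
        A=A,
        matcher=matcher,
        rng_seed=params.seed,
        r0_min=r0_min,
        conflict_dist=params.conflict_radius_fraction * r0_min,
        grow_region=region.inflate(geom.outer_radius),
    )
    state._all_hash = _SpatialHash(geom.outer_radius)
    state._ext_hash = _SpatialHash(geom.outer_radius)
    state._conflict_hash = _SpatialHash(max(state.conflict_dist, 1e-12))
    state._rep_offsets = representative_offsets(geom)
    state._neighbors = neighbor_table

    rng = np.random.default_rng(params.seed)
    row = int(rng.integers(sample.n))
    cx, cy = region.center
    seed_elem = sample.element(row)
    center_idx = state._add_element(
        cx, cy, seed_elem.type_id,
        (seed_elem.dbh, seed_elem.height, seed_elem.crown_width),
    )
    state.center_id = center_idx
    offsets, _, ntypes, nattrs = neighbor_table[row]
    for k in range(len(offsets)):
        state._add_element(
            cx + offsets[k, 0], cy + offsets[k, 1], ntypes[k], nattrs[k]
        )
    state._mark_extended(center_idx)
    logger.debug(
        "initialized with sample row %d: %d elements, r0=%.4g (outer %.4g)",
        row, state.n, geom.r0, geom.outer_radius,
    )
    return state


def select_extending_element(state: SynthesisState) -> Optional[Element]:
    """Unextended in-region element nearest the centre; None when exhausted.

    Ties in distance break toward the lowest element id. Does not mutate the
    growth; already-extended heap entries are discarded lazily.
    """
    heap = state._heap
    while heap and state.extended_flags[heap[0][1]]:
        heapq.heappop(heap)
    if not heap:
        return None
    return state._element(heap[0][1])


def determine_known_grids(
    state: SynthesisState, extending: Element,
    geom: Optional[NeighborhoodGeometry] = None,
    coverage: str = "representative",
) -> np.ndarray:
    """Boolean mask of grids covered by previously extended neighborhoods.

    With ``coverage="representative"`` a grid is determined iff its
    representative point lies strictly within one outer radius of ANY
    previously extended element (the union of all overlaps). With
    ``coverage="full"`` the grid's four corners must be covered as well — a
    conservative variant that never marks a partially covered grid, so
    determined counts are complete. The growth loop uses the conservative
    test: optimistic masks under-count the query exactly where coverage is
    partial, which biases matching toward sparse sample neighborhoods and
    bleeds density out of the synthesis.
    """
    geom = geom or state.geom
    if not state.extended_ids:
        raise ValueError("no extended elements yet: initialize first")
    R = geom.outer_radius
    ex, ey = extending.x, extending.y
    cand = state._near(state._ext_hash, ex, ey, 2.0 * R)
    if cand.size == 0:
        return np.zeros(geom.n_bins, dtype=bool)
    ext_xy = state.points.xy[cand]

    def covered(pts: np.ndarray) -> np.ndarray:
        d = (pts + (ex, ey))[:, None, :] - ext_xy[None, :, :]
        return (np.hypot(d[..., 0], d[..., 1]) < R).any(axis=1)

    mask = covered(state._rep_offsets)
    if coverage == "full":
        shells, sectors = np.divmod(np.arange(geom.n_bins), geom.n_sectors)
        for ds, da in ((0, 0), (0, 1), (1, 0), (1, 1)):
            rad = (shells + ds) * geom.r0
            ang = (sectors + da) * geom.sector_width
            mask &= covered(
                np.column_stack((rad * np.cos(ang), rad * np.sin(ang)))
            )
    elif coverage != "representative":
        raise ValueError("coverage must be 'representative' or 'full'")
    return mask


def _query_histograms(state: SynthesisState, extending: Element) -> np.ndarray:
    """(n_types, n_bins) neighbor counts around the extending element."""
    geom = state.geom
    order = state.matcher.type_order
    counts = np.zeros((len(order), geom.n_bins), dtype=float)
    idx = state._near(state._all_hash, extending.x, extending.y, geom.outer_radius)
    idx = idx[idx != extending.id]
    if idx.size:
        d = state.points.xy[idx] - (extending.x, extending.y)
        bins = assign_bins(d[:, 0], d[:, 1], geom)
        tpos = {int(t): k for k, t in enumerate(order)}
        trows = np.asarray([tpos[state.type_id_list[i]] for i in idx])
        ok = bins >= 0
        np.add.at(counts, (trows[ok], bins[ok]), 1.0)
    return counts


def extend_once(
    state: SynthesisState,
    sample: Optional[VectorPattern] = None,
    A: Optional[SimilarityMatrix] = None,
    params: Optional[SynthesisParams] = None,
) -> SynthesisState:
    """One extension: match the nearest unextended element and replenish the
    not-yet-covered part of its neighborhood with the matching element's
    neighbors.

    The determined-grid mask steers the matching; the copy filter is exact:
    a copy is dropped when it lands inside a previously extended element's
    disc (that territory is already complete — re-pasting it would double
    density), outside the growth region, or strictly within the conflict
    distance of an existing element. Attributes (DBH, height, crown width)
    are carried over verbatim from the sample neighbor each copy originates
    from.
    """
    del sample, A, params  # bound into state at initialization
    extending = select_extending_element(state)
    if extending is None:
        raise ValueError("nothing to extend: all in-region elements extended")
    mask = determine_known_grids(state, extending, coverage="full")
    query = _query_histograms(state, extending)
    row, dist = state.matcher.best_match(
        query, mask, state.type_id_list[extending.id]
    )
    offsets, _, ntypes, nattrs = state._neighbors[row]
    added = 0
    grow = state.grow_region
    R = state.geom.outer_radius
    for k in range(len(offsets)):
        x = extending.x + offsets[k, 0]
        y = extending.y + offsets[k, 1]
        if state._near(state._ext_hash, x, y, R).size:
            continue  # already-replenished territory keeps its contents
        if not (grow.x_min <= x <= grow.x_max and grow.y_min <= y <= grow.y_max):
            continue
        if state._near(state._conflict_hash, x, y, state.conflict_dist).size:
            continue
        state._add_element(x, y, ntypes[k], nattrs[k])
        added += 1
    state._mark_extended(extending.id)
    state.n_extensions += 1
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "extension %d: element %d matched sample row %d "
            "(distance %.4g), %d/%d copies kept, %d elements total",
            state.n_extensions, extending.id, row, dist,
            added, len(offsets), state.n,
        )
    return state


def synthesize(
    sample: VectorPattern, region, params: Optional[SynthesisParams] = None
) -> VectorPattern:
    """Grow a full pattern over ``region`` from ``sample``; clip and return.

    Runs extensions until every element inside the region has been extended
    (or ``max_extensions`` is hit). The result is reproducible for a fixed
    seed and contains only species present in the sample.
    """
    params = params or SynthesisParams()
    state = initialize_synthesis(sample, region, params)
    while select_extending_element(state) is not None:
        if (
            params.max_extensions is not None
            and state.n_extensions >= params.max_extensions
        ):
            logger.debug("stopping at max_extensions=%d", params.max_extensions)
            break
        extend_once(state)
    logger.debug(
        "synthesis finished: %d extensions, %d elements before clipping",
        state.n_extensions, state.n,
    )
    return state.pattern.subset(state.target_region, renumber=True)
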