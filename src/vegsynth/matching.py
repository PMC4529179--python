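"""Histogram comparison and matching-element search.

The distance between two neighborhood histograms p, q is a quadratic form

    d_A^2(p, q) = (p - q) . A . (p - q)^T,      a_ij = exp(-sigma * d(i, j)),

where d(i, j) is a grid-to-grid distance |shell_i - shell_j| + |sector_i -
sector_j|. With A = I this reduces to the squared Euclidean distance; the
exponential off-diagonal terms let counts in adjacent grids partially offset
each other, a deliberate blur that suppresses error accumulation during
synthesis. sigma is an empirical smoothing parameter, sensible between 1 and
10, default 5.0.

Two sector-distance conventions are offered: ``literal`` takes |Δsector| as
written above; ``circular`` wraps the sector difference around the disc
(sectors 0 and n-1 are adjacent). Literal is the default.

For multi-species patterns, one histogram per species is compared and the
per-species distances are combined as a weighted sum
``d_z = sum_t w_t * d_t``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np

from .geometry import (
    GridIndex,
    NeighborhoodGeometry,
    NeighborhoodHistogramSet,
    sample_histogram_table,
)
from .pattern import Element, VectorPattern

__all__ = [
    "SimilarityMatrix",
    "MatchWeights",
    "grid_distance",
    "build_similarity_matrix",
    "histogram_distance",
    "combined_distance",
    "find_matching_element",
    "SampleMatcher",
]

SECTOR_MODES = ("literal", "circular")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Grid-correlation weights for the histogram quadratic form."""

    A: np.ndarray
    sigma: float
    mode: str = "literal"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")

    @property
    def n_bins(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class MatchWeights:
    """Non-negative per-species weights of the combined distance."""

    w: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.w:
            raise ValueError("weights must not be empty")
        if any(v < 0 for v in self.w.values()):
            raise ValueError("weights must be non-negative")
        if not any(v > 0 for v in self.w.values()):
            raise ValueError("at least one weight must be strictly positive")

    @staticmethod
    def uniform(type_ids) -> "MatchWeights":
        type_ids = list(type_ids)
        return MatchWeights({int(t): 1.0 / len(type_ids) for t in type_ids})

    def vector(self, type_order) -> np.ndarray:
        try:
            return np.array([self.w[int(t)] for t in type_order], dtype=float)
        except KeyError as exc:
            raise ValueError(f"missing weight for type {exc.args[0]}") from exc


def grid_distance(i: GridIndex, j: GridIndex, mode: str = "literal",
                  n_sectors: int = 8) -> float:
    """|Δshell| + |Δsector|, optionally wrapping the sector difference."""
    if mode not in SECTOR_MODES:
        raise ValueError(f"mode must be one of {SECTOR_MODES}")
    ds = abs(i.sector - j.sector)
    if mode == "circular":
        ds = min(ds, n_sectors - ds)
    return float(abs(i.shell - j.shell) + ds)


def build_similarity_matrix(
    geom: NeighborhoodGeometry, sigma: float = 5.0, mode: str = "literal"
) -> SimilarityMatrix:
    """A[b_i, b_j] = exp(-sigma * d(grid_i, grid_j)); symmetric, unit diagonal."""
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    if mode not in SECTOR_MODES:
        raise ValueError(f"mode must be one of {SECTOR_MODES}")
    bins = np.arange(geom.n_bins)
    shells, sectors = np.divmod(bins, geom.n_sectors)
    d_shell = np.abs(shells[:, None] - shells[None, :])
    d_sector = np.abs(sectors[:, None] - sectors[None, :])
    if mode == "circular":
        d_sector = np.minimum(d_sector, geom.n_sectors - d_sector)
    A = np.exp(-sigma * (d_shell + d_sector))
    return SimilarityMatrix(A=A, sigma=float(sigma), mode=mode)


def histogram_distance(
    p, q, A: SimilarityMatrix, mask=None
) -> float:
    """Quadratic-form distance restricted to the determined (masked) bins.

    Undetermined bins contribute nothing: the form is evaluated on the masked
    submatrix, so unknowable counts never penalize a candidate.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.shape[0] != A.n_bins:
        raise ValueError("p, q and A must share one bin count")
    if mask is None:
        mask = np.ones(A.n_bins, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != A.n_bins:
        raise ValueError("mask length must equal the bin count")
    r = (p - q)[mask]
    return float(r @ A.A[np.ix_(mask, mask)] @ r)


def combined_distance(
    dists: Mapping[int, float], weights: MatchWeights
) -> float:
    """Weighted sum of per-species histogram distances."""
    total = 0.0
    for t, d in dists.items():
        if int(t) not in weights.w:
            raise ValueError(f"missing weight for type {t}")
        total += weights.w[int(t)] * float(d)
    return total


class SampleMatcher:
    """Pre-indexed sample pattern for repeated matching-element queries.

    Computes every sample element's per-species histogram once and answers
    argmin queries with one vectorized quadratic form per call. Candidates
    are restricted to the required species; ties break toward the lowest
    element id.
    """

    def __init__(
        self,
        sample: VectorPattern,
        geom: NeighborhoodGeometry,
        A: SimilarityMatrix,
        weights: Optional[MatchWeights] = None,
        periodic: bool = False,
    ) -> None:
        if A.n_bins != geom.n_bins:
            raise ValueError("similarity matrix does not fit the geometry")
        self.sample = sample
        self.geom = geom
        self.A = A
        self.periodic = periodic
        self.type_order = sample.type_ids
        self.weights = weights or MatchWeights.uniform(self.type_order)
        self._wvec = self.weights.vector(self.type_order)
        # (n, T, n_bins) histogram table, rows ordered by element id so that
        # np.argmin's first-hit rule implements the lowest-id tie-break
        order = np.argsort(sample.ids, kind="stable")
        self._row_index = order
        self._hists = sample_histogram_table(
            sample, geom, self.type_order, periodic=periodic
        )[order]
        self._types = sample.type_id_array[order]
        self._cand: Dict[int, np.ndarray] = {
            int(t): np.flatnonzero(self._types == t) for t in self.type_order
        }
        # total neighbor count per candidate: the tie-break favors the most
        # informative match (sample-border elements with truncated
        # neighborhoods would otherwise win ties and starve the growth)
        self._nbr_total = self._hists.sum(axis=(1, 2))

    def best_match(
        self, query: np.ndarray, mask: np.ndarray, required_type: int
    ) -> tuple[int, float]:
        """(pattern row index, distance) of the best same-species candidate.

        ``query`` has shape (n_types, n_bins) in this matcher's type order.
        """
        cand = self._cand.get(int(required_type))
        if cand is None or cand.size == 0:
            raise ValueError(f"sample has no element of type {required_type}")
        mask = np.asarray(mask, dtype=bool)
        m = np.flatnonzero(mask)
        if m.size == 0:
            # nothing determined: every candidate ties at distance 0
            k = int(np.argmax(self._nbr_total[cand]))
            return int(self._row_index[cand[k]]), 0.0
        Am = self.A.A[np.ix_(m, m)]
        r = self._hists[cand][:, :, m] - query[None, :, m]
        per_type = np.einsum("ctb,bd,ctd->ct", r, Am, r)
        d = per_type @ self._wvec
        ties = np.flatnonzero(d == d.min())
        # richest neighborhood first, then lowest id (argmax's first hit)
        k = int(ties[np.argmax(self._nbr_total[cand[ties]])])
        return int(self._row_index[cand[k]]), float(d[k])


def find_matching_element(
    sample: VectorPattern,
    query: NeighborhoodHistogramSet,
    A: SimilarityMatrix,
    weights: Optional[MatchWeights] = None,
    required_type: int = 0,
    geom: Optional[NeighborhoodGeometry] = None,
    matcher: Optional[SampleMatcher] = None,
) -> Element:
    """Sample element of ``required_type`` minimizing the combined distance.

    The query's determined-bin mask restricts every per-species comparison.
    A prebuilt :class:`SampleMatcher` may be passed to amortize the sample
    analysis across calls.
    """
    if matcher is None:
        if geom is None:
            nb = A.n_bins
            # reconstruct a geometry compatible with the matrix shape
            geom = NeighborhoodGeometry(r0=1.0, n_sectors=8, n_shells=nb // 8)
        matcher = SampleMatcher(sample, geom, A, weights)
    q = query.stacked(matcher.type_order)
    row, _ = matcher.best_match(q, query.mask, required_type)
    return sample.element(row)
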