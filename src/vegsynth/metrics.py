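"""Quantitative evaluation: density, aggregation index and PCT.DEV.

Two forestry indices summarise a stand's distribution:

* **density** — element count per unit area, with areas expressed in
  sample-area units (the sample region is the 1x1 unit).
* **aggregation index** — a centred Ripley statistic ``L(d) - d`` with
  ``L(d) = sqrt(K(d) / pi)`` and ``K`` the isotropic edge-corrected
  estimator. Negative values indicate regularity (uniform spacing), values
  near zero complete spatial randomness, positive values clustering.

Preservation of an index between a sample and a synthesized pattern is
scored as the percentage deviation

    D = |(I1 + I2 + I3) / 3 - Is| / |Is| * 100,

where Is is the sample's index and I1..I3 are synthesis indices measured on
patches of increasing area. The patch protocol follows the evaluation design:
synthesize one large master pattern, randomly place ``n_patches`` square
windows of each size inside it, average the per-window indices, and compare
the averages against the sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .pattern import Region, VectorPattern

__all__ = [
    "density",
    "ripley_k",
    "aggregation_index",
    "pct_dev",
    "format_pct_dev",
    "EvaluationReport",
    "evaluate_synthesis",
]


def density(
    pattern: VectorPattern,
    region=None,
    type_filter: Optional[int] = None,
) -> float:
    """Elements per unit area inside ``region`` (closed bounds).

    ``type_filter`` restricts the count to one species; None counts all.
    """
    region = Region.from_any(region) if region is not None else pattern.region
    if region.area <= 0:
        raise ValueError("region area must be strictly positive")
    if pattern.n == 0:
        return 0.0
    keep = region.contains(pattern.xy[:, 0], pattern.xy[:, 1])
    if type_filter is not None:
        keep &= pattern.type_id_array == type_filter
    return float(np.count_nonzero(keep)) / region.area


def _isotropic_weights(xy_i: np.ndarray, d_ij: np.ndarray, region: Region) -> np.ndarray:
    """Fraction of each circle's circumference lying inside the rectangle.

    Circle k is centred at ``xy_i[k]`` with radius ``d_ij[k]``. Valid for
    radii below half the rectangle's shorter side (at most two adjacent
    edges can cut a circle).
    """
    r = d_ij
    e = np.stack(
        [
            xy_i[:, 0] - region.x_min,
            region.x_max - xy_i[:, 0],
            xy_i[:, 1] - region.y_min,
            region.y_max - xy_i[:, 1],
        ],
        axis=1,
    )
    with np.errstate(invalid="ignore"):
        ratio = np.clip(e / r[:, None], -1.0, 1.0)
    cut = e < r[:, None]
    # arc outside across each cutting edge
    outside = np.where(cut, 2.0 * np.arccos(ratio), 0.0).sum(axis=1)
    # corners inside the circle are double-counted by their two edges
    for ex, ey in ((0, 2), (0, 3), (1, 2), (1, 3)):
        corner_in = e[:, ex] ** 2 + e[:, ey] ** 2 < r**2
        overlap = (
            0.5 * np.pi
            - np.arcsin(ratio[:, ex])
            - np.arcsin(ratio[:, ey])
        )
        outside = np.where(corner_in, outside - overlap, outside)
    return 1.0 - outside / (2.0 * np.pi)


def ripley_k(pattern: VectorPattern, region, d: float) -> float:
    """Isotropic edge-corrected Ripley K at distance ``d``.

    K(d) = |W| / (n (n - 1)) * sum over ordered pairs with ||x_i - x_j|| <= d
    of 1 / w_ij, where w_ij is the proportion of the circle centred at x_i
    through x_j that lies inside the window W.
    """
    region = Region.from_any(region)
    if pattern.n < 2:
        raise ValueError("pattern too small: need at least 2 elements")
    if not 0.0 < d < 0.5 * min(region.width, region.height):
        raise ValueError(
            "d must lie in (0, half the region's shorter side)"
        )
    xy = pattern.xy
    tree = cKDTree(xy)
    pairs = tree.query_pairs(d, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d_ij = np.hypot(*(xy[i] - xy[j]).T)
    w_ij = _isotropic_weights(xy[i], d_ij, region)
    w_ji = _isotropic_weights(xy[j], d_ij, region)
    n = pattern.n
    return float(region.area * (1.0 / w_ij + 1.0 / w_ji).sum() / (n * (n - 1)))


def aggregation_index(pattern: VectorPattern, region, d: float) -> float:
    """Centred Ripley statistic L(d) - d.

    Sign convention: < 0 uniform/regular, > 0 aggregated/clustered,
    approximately 0 random (CSR).
    """
    k = ripley_k(pattern, region, d)
    return float(np.sqrt(k / np.pi) - d)


def pct_dev(I_s: float, I_1: float, I_2: float, I_3: float) -> float:
    """Percentage deviation of the mean synthesis index from the sample's.

    Returns the raw (unrounded) value; see :func:`format_pct_dev` for the
    reporting precision.
    """
    if I_s == 0:
        raise ValueError("undefined deviation: sample index is zero")
    return abs((I_1 + I_2 + I_3) / 3.0 - I_s) / abs(I_s) * 100.0


def format_pct_dev(D: float) -> float:
    """Reporting precision: one decimal, two below 0.1 %."""
    return round(D, 2) if D < 0.1 else round(D, 1)


@dataclass(frozen=True)
class EvaluationReport:
    """Sample index, per-patch-size synthesis means, and their PCT.DEV."""

    sample_index: float
    patch_means: Dict[float, float]
    pct_dev: float
    index_name: str = "index"

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "sample": self.sample_index,
            "synthesis": {str(k): v for k, v in self.patch_means.items()},
            "pct_dev": self.pct_dev,
            "pct_dev_display": format_pct_dev(self.pct_dev),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Plain-text row mirroring the evaluation tables' column order."""
        sizes = sorted(self.patch_means)
        head = ["Sample(1x1)"] + [f"Synthesis({s:g}x{s:g})" for s in sizes]
        vals = [f"{self.sample_index:.6g}"] + [
            f"{self.patch_means[s]:.6g}" for s in sizes
        ]
        head.append("PCT. DEV.")
        vals.append(f"{format_pct_dev(self.pct_dev):g}%")
        w = [max(len(a), len(b)) for a, b in zip(head, vals)]
        return "\n".join(
            "  ".join(s.rjust(width) for s, width in zip(row, w))
            for row in (head, vals)
        )


def evaluate_synthesis(
    sample: VectorPattern,
    synthesized_master: VectorPattern,
    index_fn: Callable[[VectorPattern, Region], float],
    patch_sizes: Sequence[float] = (3.0, 6.0, 10.0),
    n_patches: int = 10,
    seed: int = 0,
    index_name: str = "index",
) -> EvaluationReport:
    """Random-patch evaluation of a synthesized master pattern M.

    For each patch size ``a``, draws ``n_patches`` uniformly placed,
    axis-aligned, fully interior a x a windows of M (distinct positions, by
    rejection of exact duplicates), evaluates ``index_fn(sub_pattern,
    window)`` on each and averages. The averages are compared against
    ``index_fn`` on the sample via :func:`pct_dev`.
    """
    master_region = synthesized_master.region
    biggest = max(patch_sizes)
    if biggest >= min(master_region.width, master_region.height):
        raise ValueError(
            f"patch size {biggest:g} does not fit strictly inside the "
            f"master region {master_region.width:g} x {master_region.height:g}"
        )
    rng = np.random.default_rng(seed)
    means: Dict[float, float] = {}
    for a in patch_sizes:
        a = float(a)
        seen: set[tuple[float, float]] = set()
        vals = []
        while len(vals) < n_patches:
            x0 = rng.uniform(master_region.x_min, master_region.x_max - a)
            y0 = rng.uniform(master_region.y_min, master_region.y_max - a)
            if (x0, y0) in seen:
                continue
            seen.add((x0, y0))
            window = Region(x0, y0, x0 + a, y0 + a)
            vals.append(index_fn(synthesized_master.subset(window), window))
        means[a] = float(np.mean(vals))
    I_s = index_fn(sample, sample.region)
    if I_s == 0:
        raise ValueError("undefined deviation: sample index is zero")
    # identical to pct_dev for the standard three patch sizes
    D = abs(float(np.mean(list(means.values()))) - I_s) / abs(I_s) * 100.0
    return EvaluationReport(
        sample_index=float(I_s),
        patch_means=means,
        pct_dev=float(D),
        index_name=index_name,
    )
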