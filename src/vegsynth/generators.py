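"""Synthetic sample-pattern generators.

Stand-ins for designed or field-measured sample stands, one per canonical
distribution class:

* :func:`gen_regular` — square lattice (plantation-like regular spacing),
  optionally jittered.
* :func:`gen_poisson` — homogeneous Poisson process (complete spatial
  randomness).
* :func:`gen_cluster` — Matérn cluster process: Poisson parents, each with a
  Poisson number of offspring scattered uniformly in a disc.
* :func:`gen_two_type` — a two-species stand: hard-core arbors (tall trees
  keeping their distance) over clustered shrubs, optionally with lognormal
  DBH / height / crown-width attributes.

Every generator is seeded and deterministic, respects its region bounds and
produces unique consecutive ids.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pattern import Region, VectorPattern

__all__ = ["gen_regular", "gen_poisson", "gen_cluster", "gen_two_type"]

UNIT_REGION = Region(0.0, 0.0, 1.0, 1.0)

#: Lognormal attribute defaults (mean of log, sd of log), per species role.
#: Arbors sized like mature Chinese pine (DBH in cm, height and crown in m);
#: shrubs an order of magnitude smaller.
ARBOR_ATTRS = {"dbh": (math.log(25.0), 0.3), "height": (math.log(12.0), 0.25),
               "crown_width": (math.log(3.0), 0.3)}
SHRUB_ATTRS = {"dbh": (math.log(3.0), 0.3), "height": (math.log(1.5), 0.25),
               "crown_width": (math.log(0.8), 0.3)}


def _as_pattern(xy: np.ndarray, type_ids, region: Region,
                attrs: Optional[dict] = None) -> VectorPattern:
    n = len(xy)
    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "x": xy[:, 0] if n else np.empty(0),
            "y": xy[:, 1] if n else np.empty(0),
            "type_id": np.broadcast_to(np.asarray(type_ids, dtype=np.int64), (n,)),
        }
    )
    for col, vals in (attrs or {}).items():
        df[col] = vals
    return VectorPattern(df, region)


def gen_regular(
    density_per_unit: int,
    region=UNIT_REGION,
    jitter: float = 0.0,
    seed: int = 0,
) -> VectorPattern:
    """Square lattice with ``density_per_unit`` elements per unit area.

    The density must be a perfect square so the lattice spacing is
    ``1 / sqrt(density)``. Lattice nodes sit at cell centres; ``jitter``
    displaces each node uniformly in ``[-jitter, jitter]`` per axis (clipped
    to the region).
    """
    region = Region.from_any(region)
    side = math.isqrt(int(density_per_unit))
    if side * side != int(density_per_unit):
        raise ValueError(
            f"density {density_per_unit} is not a perfect square"
        )
    spacing = 1.0 / side
    nx = int(round(region.width / spacing))
    ny = int(round(region.height / spacing))
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xy = np.column_stack(
        [
            region.x_min + (ix.ravel() + 0.5) * spacing,
            region.y_min + (iy.ravel() + 0.5) * spacing,
        ]
    )
    if jitter > 0:
        rng = np.random.default_rng(seed)
        xy = xy + rng.uniform(-jitter, jitter, size=xy.shape)
        xy[:, 0] = np.clip(xy[:, 0], region.x_min, region.x_max)
        xy[:, 1] = np.clip(xy[:, 1], region.y_min, region.y_max)
    return _as_pattern(xy, 0, region)


def gen_poisson(intensity: float, region=UNIT_REGION, seed: int = 0) -> VectorPattern:
    """Homogeneous Poisson process: count ~ Poisson(intensity * area),
    positions i.i.d. uniform over the region."""
    if intensity <= 0:
        raise ValueError("intensity must be strictly positive")
    region = Region.from_any(region)
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(intensity * region.area))
    xy = np.column_stack(
        [
            rng.uniform(region.x_min, region.x_max, n),
            rng.uniform(region.y_min, region.y_max, n),
        ]
    )
    return _as_pattern(xy, 0, region)


def gen_cluster(
    parent_intensity: float,
    mean_offspring: float,
    cluster_radius: float,
    region=UNIT_REGION,
    seed: int = 0,
) -> VectorPattern:
    """Matérn cluster process with expected intensity
    ``parent_intensity * mean_offspring``.

    Parents form a Poisson process on the region inflated by the cluster
    radius (so clusters centred just outside still contribute), each parent
    receives a Poisson(mean_offspring) brood scattered uniformly in a disc
    of ``cluster_radius``; offspring falling outside the region are dropped.
    """
    if min(parent_intensity, mean_offspring, cluster_radius) <= 0:
        raise ValueError("all cluster parameters must be strictly positive")
    region = Region.from_any(region)
    rng = np.random.default_rng(seed)
    outer = region.inflate(cluster_radius)
    n_parents = int(rng.poisson(parent_intensity * outer.area))
    px = rng.uniform(outer.x_min, outer.x_max, n_parents)
    py = rng.uniform(outer.y_min, outer.y_max, n_parents)
    brood = rng.poisson(mean_offspring, n_parents)
    cx = np.repeat(px, brood)
    cy = np.repeat(py, brood)
    n = len(cx)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    rad = cluster_radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    xy = np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)])
    keep = region.contains(xy[:, 0], xy[:, 1])
    return _as_pattern(xy[keep], 0, region)


def _hardcore(intensity: float, min_dist: float, region: Region,
              rng: np.random.Generator) -> np.ndarray:
    """Minimum-distance sequential thinning of a Poisson proposal stream."""
    target = intensity * region.area
    n_prop = int(rng.poisson(target)) if min_dist <= 0 else max(
        int(np.ceil(3 * target)), 1
    )
    xs = rng.uniform(region.x_min, region.x_max, n_prop)
    ys = rng.uniform(region.y_min, region.y_max, n_prop)
    kept: list[tuple[float, float]] = []
    tree: Optional[cKDTree] = None
    for k in range(n_prop):
        if len(kept) >= target:
            break
        p = (xs[k], ys[k])
        if kept:
            if tree is None or len(kept) % 64 == 0:
                tree = cKDTree(np.asarray(kept))
            # check recent points not yet in the tree, then the tree
            recent = kept[(len(kept) // 64) * 64:]
            if recent and np.min(
                np.hypot(*(np.asarray(recent) - p).T)
            ) < min_dist:
                continue
            if tree.query_ball_point(p, min_dist):
                continue
        kept.append(p)
    if len(kept) < 0.8 * target:
        warnings.warn(
            f"hard-core packing infeasible: placed {len(kept)} of "
            f"{target:.0f} requested arbors at min_dist={min_dist}",
            stacklevel=3,
        )
    return np.asarray(kept).reshape(-1, 2)


def gen_two_type(
    arbor_intensity: float = 172.0,
    arbor_min_dist: float = 0.04,
    shrub_parent_intensity: float = 4.0,
    shrub_mean_offspring: float = 4.75,
    shrub_cluster_radius: float = 0.06,
    region=UNIT_REGION,
    seed: int = 0,
    attributes: bool = False,
) -> VectorPattern:
    """Two-species stand: hard-core arbors (type 0) + clustered shrubs (type 1).

    Defaults emulate a mixed stand with ~172 arbors and ~19 shrubs per unit
    area. With ``attributes=True`` each element receives lognormal DBH,
    height and crown width (arbor- or shrub-scaled).
    """
    if min(arbor_intensity, arbor_min_dist, shrub_parent_intensity,
           shrub_mean_offspring, shrub_cluster_radius) <= 0:
        raise ValueError("all generator parameters must be strictly positive")
    region = Region.from_any(region)
    rng = np.random.default_rng(seed)
    arbors = _hardcore(arbor_intensity, arbor_min_dist, region, rng)
    shrubs = gen_cluster(
        shrub_parent_intensity,
        shrub_mean_offspring,
        shrub_cluster_radius,
        region,
        seed=int(rng.integers(2**31)),
    ).xy
    xy = np.vstack([arbors, shrubs])
    type_ids = np.concatenate(
        [np.zeros(len(arbors), dtype=np.int64), np.ones(len(shrubs), dtype=np.int64)]
    )
    attrs = None
    if attributes:
        attrs = {}
        for col in ("dbh", "height", "crown_width"):
            mu_a, sd_a = ARBOR_ATTRS[col]
            mu_s, sd_s = SHRUB_ATTRS[col]
            vals = np.where(
                type_ids == 0,
                rng.lognormal(mu_a, sd_a, len(xy)),
                rng.lognormal(mu_s, sd_s, len(xy)),
            )
            attrs[col] = vals
    return _as_pattern(xy, type_ids, region, attrs)
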