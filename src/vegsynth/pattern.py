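"""Core containers: elements, regions and vector patterns.

A *vector pattern* is the unit of both input and output: a set of discrete
elements (one per plant) with 2-D positions, an integer species/type id and
optional per-tree attributes (DBH, height, crown width), together with the
axis-aligned rectangular region the pattern lives in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

ATTRIBUTE_COLUMNS = ("dbh", "height", "crown_width")
REQUIRED_COLUMNS = ("id", "x", "y", "type_id")


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle with strictly positive width and height."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"region must have positive width and height, got {self}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def contains(self, x, y) -> np.ndarray:
        """Vectorized closed-bounds membership test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )

    def inflate(self, margin: float) -> "Region":
        return Region(
            self.x_min - margin,
            self.y_min - margin,
            self.x_max + margin,
            self.y_max + margin,
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @staticmethod
    def from_any(region: Union["Region", Sequence[float]]) -> "Region":
        if isinstance(region, Region):
            return region
        vals = [float(v) for v in region]
        if len(vals) != 4:
            raise ValueError("region must be (x_min, y_min, x_max, y_max)")
        return Region(*vals)


@dataclass(frozen=True)
class Element:
    """One plant: position, species code and optional size attributes."""

    id: int
    x: float
    y: float
    type_id: int = 0
    dbh: Optional[float] = None
    height: Optional[float] = None
    crown_width: Optional[float] = None

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


class VectorPattern:
    """A set of elements plus the rectangular region they occupy.

    Backed by a :class:`pandas.DataFrame` with columns ``id, x, y, type_id``
    and optionally ``dbh, height, crown_width``. Invariants checked at
    construction: unique ids, positions inside the region (closed bounds) and
    non-negative attributes where present.
    """

    def __init__(self, elements, region) -> None:
        self.region = Region.from_any(region)
        if isinstance(elements, pd.DataFrame):
            df = elements.copy()
        else:
            df = pd.DataFrame(
                [
                    {
                        "id": e.id,
                        "x": e.x,
                        "y": e.y,
                        "type_id": e.type_id,
                        "dbh": e.dbh,
                        "height": e.height,
                        "crown_width": e.crown_width,
                    }
                    for e in elements
                ],
                columns=list(REQUIRED_COLUMNS) + list(ATTRIBUTE_COLUMNS),
            )
            # drop attribute columns that are entirely absent
            for col in ATTRIBUTE_COLUMNS:
                if col in df and df[col].isna().all():
                    df = df.drop(columns=[col])
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = df.reset_index(drop=True)
        df["id"] = df["id"].astype(np.int64)
        df["type_id"] = df["type_id"].astype(np.int64)
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
        for col in ATTRIBUTE_COLUMNS:
            if col in df.columns:
                df[col] = df[col].astype(float)
                vals = df[col].to_numpy()
                if np.any(vals[~np.isnan(vals)] < 0):
                    raise ValueError(f"attribute {col!r} must be non-negative")
        if df["id"].duplicated().any():
            raise ValueError("element ids must be unique within a pattern")
        if len(df) and not self.region.contains(df["x"], df["y"]).all():
            raise ValueError("all element positions must lie inside the region")
        self._df = df

    # -- accessors ---------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def n(self) -> int:
        return len(self._df)

    def __len__(self) -> int:
        return self.n

    @property
    def xy(self) -> np.ndarray:
        return self._df[["x", "y"]].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self._df["id"].to_numpy()

    @property
    def type_id_array(self) -> np.ndarray:
        return self._df["type_id"].to_numpy()

    @property
    def type_ids(self) -> tuple[int, ...]:
        """Sorted distinct species codes present in the pattern."""
        return tuple(sorted(set(self._df["type_id"].tolist())))

    @property
    def has_attributes(self) -> bool:
        return any(c in self._df.columns for c in ATTRIBUTE_COLUMNS)

    def element(self, index: int) -> Element:
        row = self._df.iloc[index]
        return Element(
            id=int(row["id"]),
            x=float(row["x"]),
            y=float(row["y"]),
            type_id=int(row["type_id"]),
            dbh=_opt(row.get("dbh")),
            height=_opt(row.get("height")),
            crown_width=_opt(row.get("crown_width")),
        )

    def __iter__(self) -> Iterator[Element]:
        return (self.element(i) for i in range(self.n))

    def element_by_id(self, eid: int) -> Element:
        idx = np.flatnonzero(self.ids == eid)
        if idx.size == 0:
            raise KeyError(f"no element with id {eid}")
        return self.element(int(idx[0]))

    def subset(self, region, renumber: bool = False) -> "VectorPattern":
        """Elements inside ``region`` (closed bounds), as a new pattern."""
        region = Region.from_any(region)
        keep = region.contains(self._df["x"], self._df["y"])
        df = self._df[keep].reset_index(drop=True)
        if renumber:
            df = df.assign(id=np.arange(len(df), dtype=np.int64))
        return VectorPattern(df, region)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"VectorPattern(n={self.n}, types={list(self.type_ids)}, "
            f"region={self.region.as_tuple()})"
        )


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    return None if np.isnan(value) else value
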