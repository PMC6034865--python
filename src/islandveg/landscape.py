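"""Landscape-structure predictors from island geometry and wind climate.

All geometry is planar and metric (coordinates in metres).  Islands are
shapely polygons (circles are a convenient special case for synthetic
seascapes).  Three predictors describe a plot's seascape context:

* REI — relative wave-exposure index, the product-sum over the eight compass
  directions of wind speed, wind frequency and fetch (open-water distance),
* PROX — FRAGSTATS-style proximity index, sum of area / distance^2 over
  landmasses within a search radius,
* DMI — edge-to-edge distance to the mainland or the nearest island of at
  least 50 ha.

Island-configuration metrics (total area, habitat area, rock and tree cover)
are carried per island and validated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

COMPASS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
#: Azimuth (radians, clockwise from north) of each compass direction.
_AZIMUTH = {d: math.radians(i * 45.0) for i, d in enumerate(COMPASS)}

LARGE_ISLAND_M2 = 500_000.0  # 50 ha


@dataclass
class IslandGeometry:
    """One landmass with its configuration metrics."""

    island_id: str
    shape: Polygon
    habitat_area: float | None = None
    rock_cover: float = 0.0
    tree_cover: float = 0.0
    is_mainland: bool = False

    def __post_init__(self) -> None:
        if self.shape.area <= 0:
            raise ValueError(f"island {self.island_id!r} has non-positive area")
        if self.habitat_area is None:
            self.habitat_area = self.shape.area
        if self.habitat_area > self.shape.area + 1e-9:
            raise ValueError(
                f"island {self.island_id!r}: habitat area exceeds island area"
            )
        for name, cov in (("rock", self.rock_cover), ("tree", self.tree_cover)):
            if not 0.0 <= cov <= 100.0:
                raise ValueError(f"{name} cover outside [0, 100]")

    @property
    def area(self) -> float:
        return self.shape.area

    @classmethod
    def circle(
        cls, island_id: str, x: float, y: float, radius: float, **kw
    ) -> "IslandGeometry":
        return cls(island_id, Point(x, y).buffer(radius, quad_segs=64), **kw)


@dataclass
class WindClimate:
    """Directional wind frequencies and mean speeds (eight compass sectors)."""

    frequency: dict[str, float]
    speed: dict[str, float]

    def __post_init__(self) -> None:
        for table, name in ((self.frequency, "frequency"), (self.speed, "speed")):
            missing = set(COMPASS) - set(table)
            if missing:
                raise ValueError(f"wind {name} missing directions {sorted(missing)}")
            if any(v < 0 for v in table.values()):
                raise ValueError(f"negative wind {name}")


def rei(wind: WindClimate, fetch: dict[str, float]) -> float:
    """Relative exposure index: sum over directions of speed * frequency * fetch."""
    missing = set(COMPASS) - set(fetch)
    if missing:
        raise ValueError(f"fetch missing directions {sorted(missing)}")
    if any(f < 0 for f in fetch.values()):
        raise ValueError("negative fetch")
    return float(
        sum(wind.speed[d] * wind.frequency[d] * fetch[d] for d in COMPASS)
    )


def fetch_by_ray_casting(
    site: Point,
    islands: list[IslandGeometry],
    max_fetch: float = 50_000.0,
    exclude: str | None = None,
) -> dict[str, float]:
    """Open-water distance from a site in each compass direction.

    A ray is cast from the site along each direction; the fetch is the
    distance to the first intersected landmass, capped at ``max_fetch``
    (open sea).  ``exclude`` skips the island the site itself sits on.
    """
    out: dict[str, float] = {}
    for d in COMPASS:
        az = _AZIMUTH[d]
        end = Point(
            site.x + max_fetch * math.sin(az), site.y + max_fetch * math.cos(az)
        )
        ray = LineString([site, end])
        dist = max_fetch
        for isl in islands:
            if exclude is not None and isl.island_id == exclude:
                continue
            hit = ray.intersection(isl.shape)
            if not hit.is_empty:
                dist = min(dist, site.distance(hit))
        out[d] = dist
    return out


def prox(
    site: Point,
    islands: list[IslandGeometry],
    radius: float = 500.0,
    exclude: str | None = None,
) -> float:
    """Proximity index: sum of area / edge-distance^2 within the radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    total = 0.0
    for isl in islands:
        if exclude is not None and isl.island_id == exclude:
            continue
        d = site.distance(isl.shape)
        if d == 0.0:
            raise ValueError(
                f"site lies on landmass {isl.island_id!r}; exclude the home island"
            )
        if d <= radius:
            total += isl.area / d**2
    return total


def dmi(focal: IslandGeometry, landmasses: list[IslandGeometry]) -> float:
    """Edge-to-edge distance to the mainland or nearest island >= 50 ha."""
    qualifying = [
        l
        for l in landmasses
        if l.island_id != focal.island_id
        and (l.is_mainland or l.area >= LARGE_ISLAND_M2)
    ]
    if not qualifying:
        raise ValueError("no mainland or island >= 50 ha among the landmasses")
    return min(focal.shape.distance(l.shape) for l in qualifying)


def island_config(isl: IslandGeometry) -> dict[str, float]:
    """Configuration metrics (ISL_A, HAB_A, R_COV, T_COV) with unit checks."""
    return {
        "ISL_A": isl.area,
        "HAB_A": float(isl.habitat_area),
        "R_COV": isl.rock_cover,
        "T_COV": isl.tree_cover,
    }


def read_wind_csv(path) -> WindClimate:
    """Wind-climate CSV: direction, frequency, speed."""
    df = pd.read_csv(path)
    required = {"direction", "frequency", "speed"}
    if not required.issubset(df.columns):
        raise ValueError(f"wind table needs columns {sorted(required)}")
    return WindClimate(
        dict(zip(df["direction"], df["frequency"].astype(float))),
        dict(zip(df["direction"], df["speed"].astype(float))),
    )


def read_islands_csv(path) -> list[IslandGeometry]:
    """Islands CSV: island_id, x, y, radius [, rock_cover, tree_cover, is_mainland]."""
    df = pd.read_csv(path)
    required = {"island_id", "x", "y", "radius"}
    if not required.issubset(df.columns):
        raise ValueError(f"islands table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            IslandGeometry.circle(
                str(row["island_id"]),
                float(row["x"]),
                float(row["y"]),
                float(row["radius"]),
                rock_cover=float(row.get("rock_cover", 0.0)),
                tree_cover=float(row.get("tree_cover", 0.0)),
                is_mainland=bool(row.get("is_mainland", False)),
            )
        )
    return out
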