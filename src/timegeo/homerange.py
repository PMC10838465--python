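"""Percentage-convex-hull home ranges and dyadic overlap.

The "used" home range is the convex hull of the 95% of fixes closest to
the track's mean center; trimming the farthest 5% removes excursions
that would otherwise dominate the hull. Overlap between two ranges is
directional: area(x intersect y) / area(y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon


class DegenerateGeometryError(ValueError):
    """Too few or collinear points for a hull."""


@dataclass
class HomeRange:
    individual_id: str
    window: str
    polygon: Polygon
    n_points_used: int
    n_points_dropped: int

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


def hull95(
    points: pd.DataFrame,
    retain: float = 0.95,
    individual_id: str = "",
    window: str = "",
    center: str = "mean",
) -> HomeRange:
    """Convex hull of the ``retain`` fraction of fixes nearest the center.

    The floor((1-retain)*n) fixes farthest (Euclidean) from the center
    are dropped; ties on distance keep the earlier fix. ``center`` is
    the coordinate-wise mean by default, or "median".
    """
    if not (0.0 < retain <= 1.0):
        raise ValueError("retain must be in (0, 1]")
    xy = points[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    n_drop = int(np.floor((1.0 - retain) * n))
    if n - n_drop < 3:
        raise DegenerateGeometryError(
            f"{n - n_drop} points after trimming; need >= 3"
        )
    if n_drop > 0:
        ctr = np.mean(xy, axis=0) if center == "mean" else np.median(xy, axis=0)
        d = np.hypot(*(xy - ctr).T)
        # stable sort: among equal distances the later fix is dropped first
        order = np.argsort(d, kind="stable")
        keep_idx = np.sort(order[: n - n_drop])
        xy = xy[keep_idx]
    hull = MultiPoint(xy).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0.0:
        raise DegenerateGeometryError("points are collinear")
    return HomeRange(individual_id, window, hull, len(xy), n_drop)


def overlap_proportion(hx: HomeRange, hy: HomeRange) -> float:
    """area(hx intersect hy) / area(hy) — note the asymmetry in y."""
    ay = hy.polygon.area
    if ay == 0.0:
        raise DegenerateGeometryError("reference home range has zero area")
    return hx.polygon.intersection(hy.polygon).area / ay


def windowed_ranges(
    track: pd.DataFrame,
    windows: list[tuple[pd.Timestamp, pd.Timestamp, str]] | str = "M",
    retain: float = 0.95,
    individual_id: str = "",
) -> tuple[list[HomeRange], list[str]]:
    """One trimmed hull per time window.

    ``windows`` is either a list of (start, end, label) spans or the
    string "M" for calendar months. Windows with too few points after
    trimming are skipped and reported in the second return value.
    Trimming is applied per window.
    """
    if windows == "M":
        tz = track["t"].iloc[0].tz
        naive = track["t"].dt.tz_localize(None) if tz is not None else track["t"]
        spans = []
        for m in naive.dt.to_period("M").unique():
            t0, t1 = m.to_timestamp(), (m + 1).to_timestamp()
            if tz is not None:
                t0, t1 = t0.tz_localize(tz), t1.tz_localize(tz)
            spans.append((t0, t1, str(m)))
    else:
        spans = windows
    ranges: list[HomeRange] = []
    skipped: list[str] = []
    for t0, t1, label in spans:
        sub = track[(track["t"] >= t0) & (track["t"] < t1)]
        try:
            ranges.append(hull95(sub, retain, individual_id, label))
        except DegenerateGeometryError as err:
            skipped.append(f"{individual_id}/{label}: {err}")
    return ranges, skipped


def ranges_to_frame(ranges: list[HomeRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": hr.individual_id,
                "window": hr.window,
                "area_km2": hr.area_km2,
                "n_used": hr.n_points_used,
                "n_dropped": hr.n_points_dropped,
                "wkt": hr.polygon.wkt,
            }
            for hr in ranges
        ],
        columns=["id", "window", "area_km2", "n_used", "n_dropped", "wkt"],
    )
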