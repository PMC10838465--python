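"""Reading, validating and segmenting GPS telemetry.

Telemetry arrives as a delimited table with one row per fix (individual
id, timestamp, and either geographic lon/lat or projected x/y in
meters). This module turns it into a :class:`TrackSet` — per-individual,
strictly time-ordered fix sequences in a shared planar frame — and
derives per-individual movement segments (consecutive fix pairs with
duration, step length, speed and heading).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import project_lonlat

FIX_COLUMNS = ["id", "t", "x", "y", "lon", "lat"]


class SchemaError(ValueError):
    """Input table lacks required columns or has unparseable values."""


@dataclass
class IOConfig:
    """Column mapping and parsing options for telemetry tables.

    Timestamps are parsed as UTC unless ``timezone`` names another zone;
    month binning downstream follows the configured zone.
    """

    id_col: str = "id"
    time_col: str = "t"
    lon_col: str = "lon"
    lat_col: str = "lat"
    x_col: str = "x"
    y_col: str = "y"
    sep: str = ","
    timezone: str = "UTC"
    utm_zone: int | None = None


@dataclass
class TrackSet:
    """Per-individual fix tables plus sampling-interval statistics.

    ``fixes`` holds one DataFrame per individual with columns
    ``t`` (tz-aware Timestamp), ``x``, ``y`` in meters and, when the
    input was geographic, ``lon``/``lat`` in degrees. Interval
    statistics (mean, population SD of consecutive-fix gaps, hours) are
    recomputed whenever fixes change.
    """

    fixes: dict[str, pd.DataFrame] = field(default_factory=dict)
    crs: str = "local"

    @property
    def ids(self) -> list[str]:
        return list(self.fixes)

    def track(self, individual_id: str) -> pd.DataFrame:
        return self.fixes[individual_id]

    def interval_stats(self, individual_id: str) -> tuple[float, float]:
        return interval_stats(self.fixes[individual_id])

    def to_frame(self) -> pd.DataFrame:
        """Canonical long-format table (id, t, x, y, lon, lat)."""
        parts = []
        for ind, df in self.fixes.items():
            out = df.copy()
            out.insert(0, "id", ind)
            for col in ("lon", "lat"):
                if col not in out.columns:
                    out[col] = np.nan
            parts.append(out[FIX_COLUMNS])
        if not parts:
            return pd.DataFrame(columns=FIX_COLUMNS)
        return pd.concat(parts, ignore_index=True)

    def write(self, path) -> None:
        df = self.to_frame()
        df = df.copy()
        df["t"] = df["t"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
        df.to_csv(path, index=False, float_format="%.6f")


def _finalize_tracks(
    frame: pd.DataFrame, crs: str, warnings_out: list[str] | None = None
) -> TrackSet:
    ts = TrackSet(crs=crs)
    for ind, grp in frame.groupby("id", sort=True):
        grp = grp.sort_values("t", kind="mergesort")
        grp = grp.drop_duplicates(subset="t", keep="first")
        if len(grp) < 2:
            if warnings_out is not None:
                warnings_out.append(
                    f"individual {ind!r} dropped: fewer than 2 fixes"
                )
            continue
        cols = [c for c in ("t", "x", "y", "lon", "lat") if c in grp.columns]
        ts.fixes[str(ind)] = grp[cols].reset_index(drop=True)
    return ts


def read_tracks(path, config: IOConfig | None = None) -> TrackSet:
    """Read a telemetry table into a TrackSet.

    Fixes are sorted per individual, exact-duplicate timestamps are
    collapsed to the first occurrence, and lon/lat inputs are projected
    to the UTM zone of the data centroid (meters). Individuals with
    fewer than two fixes are dropped with a warning recorded on the
    returned object (``tracks._warnings``).
    """
    config = config or IOConfig()
    raw = pd.read_csv(path, sep=config.sep)

    missing = [c for c in (config.id_col, config.time_col) if c not in raw.columns]
    has_geo = config.lon_col in raw.columns and config.lat_col in raw.columns
    has_xy = config.x_col in raw.columns and config.y_col in raw.columns
    if missing or not (has_geo or has_xy):
        need = missing + ([] if has_geo or has_xy else ["lon/lat or x/y"])
        raise SchemaError(f"missing required column(s): {need}")

    t = pd.to_datetime(raw[config.time_col], utc=True, errors="coerce", format="ISO8601")
    bad = np.flatnonzero(t.isna().to_numpy())
    if bad.size:
        raise SchemaError(f"unparseable timestamp at row index {bad[0]}")
    if config.timezone != "UTC":
        t = t.dt.tz_convert(config.timezone)

    frame = pd.DataFrame({"id": raw[config.id_col].astype(str), "t": t})
    crs = "local"
    if has_xy:
        frame["x"] = pd.to_numeric(raw[config.x_col])
        frame["y"] = pd.to_numeric(raw[config.y_col])
        if has_geo:
            frame["lon"] = pd.to_numeric(raw[config.lon_col])
            frame["lat"] = pd.to_numeric(raw[config.lat_col])
    else:
        lon = pd.to_numeric(raw[config.lon_col]).to_numpy()
        lat = pd.to_numeric(raw[config.lat_col]).to_numpy()
        x, y, zone, north = project_lonlat(lon, lat, config.utm_zone)
        frame["x"], frame["y"] = x, y
        frame["lon"], frame["lat"] = lon, lat
        crs = f"utm{zone}{'n' if north else 's'}"
    if not np.isfinite(frame[["x", "y"]].to_numpy()).all():
        raise SchemaError("non-finite coordinates in input")

    warnings: list[str] = []
    ts = _finalize_tracks(frame, crs, warnings)
    ts._warnings = warnings  # type: ignore[attr-defined]
    return ts


def tracks_from_frame(frame: pd.DataFrame, crs: str = "local") -> TrackSet:
    """Build a TrackSet from an in-memory (id, t, x, y[, lon, lat]) frame."""
    return _finalize_tracks(frame, crs)


def build_segments(track: pd.DataFrame) -> pd.DataFrame:
    """Movement segments between consecutive fixes of one individual.

    Returns one row per consecutive fix pair with columns ``t_start``,
    ``t_end``, ``x1``/``y1``/``x2``/``y2``, ``dt_h`` (hours), ``dist_m``,
    ``speed`` (m/h) and ``heading`` (degrees clockwise from north).
    Zero-displacement segments get speed 0 and ``heading_valid=False``.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 fixes to build segments")
    t = pd.DatetimeIndex(track["t"]).to_numpy()
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    dt_h = ((t[1:] - t[:-1]) / np.timedelta64(1, "h")).astype(float)
    if np.any(dt_h <= 0):
        raise ValueError("timestamps not strictly increasing")
    dx = np.diff(x)
    dy = np.diff(y)
    dist = np.hypot(dx, dy)
    speed = dist / dt_h
    heading = np.degrees(np.arctan2(dx, dy)) % 360.0
    valid = dist > 0
    heading = np.where(valid, heading, np.nan)
    return pd.DataFrame(
        {
            "t_start": track["t"].iloc[:-1].to_numpy(),
            "t_end": track["t"].iloc[1:].to_numpy(),
            "x1": x[:-1],
            "y1": y[:-1],
            "x2": x[1:],
            "y2": y[1:],
            "dt_h": dt_h,
            "dist_m": dist,
            "speed": speed,
            "heading": heading,
            "heading_valid": valid,
        }
    )


def interval_stats(track: pd.DataFrame) -> tuple[float, float]:
    """Mean and population SD of consecutive-fix intervals, in hours."""
    if len(track) < 2:
        raise ValueError("need at least 2 fixes for interval statistics")
    t = pd.DatetimeIndex(track["t"]).to_numpy()
    dt_h = ((t[1:] - t[:-1]) / np.timedelta64(1, "h")).astype(float)
    return float(np.mean(dt_h)), float(np.std(dt_h))
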