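"""Dyadic interaction detection by PPA intersection.

Two animals may have met between fixes whenever their potential path
areas intersect. Each intersecting pair of PPAs is an event; the lag
between the two ellipses' start times classifies it as concurrent
(lag at or below the sampling interval) or delayed (asynchronous reuse
of the same place, binned from one day up to several weeks). Maximal
temporally continuous runs of concurrent events are traced into
interaction segments whose duration is max end time minus min start
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

HOUR = np.timedelta64(3600, "s")

#: default delayed-lag bin boundaries, hours: 1 day, 1, 2, 3 weeks
DEFAULT_LAG_BINS = (24.0, 168.0, 336.0, 504.0)


def candidate_pairs(
    ppas_a: pd.DataFrame,
    ppas_b: pd.DataFrame,
    max_lag_h: float = np.inf,
) -> np.ndarray:
    """Spatio-temporally plausible PPA pairs via a centroid k-d tree.

    Two ellipses can only intersect if their centroids are within the
    sum of the two lists' largest semi-major axes, so a radius query on
    centroids returns a guaranteed superset of the intersecting pairs;
    pairs whose start times differ by more than ``max_lag_h`` are
    discarded. Returns an (n, 2) array of (index_a, index_b).
    """
    if len(ppas_a) == 0 or len(ppas_b) == 0:
        return np.empty((0, 2), dtype=int)
    r = float(ppas_a["a"].max() + ppas_b["a"].max())
    tree = cKDTree(np.column_stack([ppas_b["cx"], ppas_b["cy"]]))
    neighbors = tree.query_ball_point(
        np.column_stack([ppas_a["cx"], ppas_a["cy"]]), r=r
    )
    ta = pd.DatetimeIndex(ppas_a["t_start"]).asi8  # ns since epoch
    tb = pd.DatetimeIndex(ppas_b["t_start"]).asi8
    ns_per_h = 3.6e12
    pairs = []
    for ia, nbrs in enumerate(neighbors):
        if not nbrs:
            continue
        nbrs = np.asarray(nbrs)
        if np.isfinite(max_lag_h):
            lag = np.abs(ta[ia] - tb[nbrs]) / ns_per_h
            nbrs = nbrs[lag <= max_lag_h]
        pairs.extend((ia, ib) for ib in nbrs)
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def ellipse_intersects(geom_a, geom_b) -> tuple[bool, float]:
    """Exact polygon intersection test with overlap area (m^2).

    A shared boundary point counts as intersecting; degenerate
    (line-shaped) PPAs intersect through their chord with area 0.
    """
    if not geom_a.intersects(geom_b):
        return False, 0.0
    return True, float(geom_a.intersection(geom_b).area)


def classify_lag(
    lag_h: float,
    concurrent_threshold_h: float = 1.0,
    lag_bins: tuple[float, ...] = DEFAULT_LAG_BINS,
) -> tuple[str, float]:
    """Classify an event's start-time lag.

    Lag at or below the concurrency threshold (the data's sampling
    interval by default) is concurrent. Otherwise the event is delayed
    and assigned the largest bin boundary <= lag (closed lower bound);
    a delayed lag below the smallest bin gets bin 0.

    Returns (kind, bin) where bin is the lag-bin boundary in hours
    (NaN for concurrent).
    """
    if concurrent_threshold_h < 0:
        raise ValueError("concurrent threshold must be >= 0")
    if lag_h <= concurrent_threshold_h:
        return "concurrent", float("nan")
    bins = np.asarray(sorted(lag_bins), dtype=float)
    eligible = bins[bins <= lag_h]
    return "delayed", float(eligible[-1]) if eligible.size else 0.0


def find_events(
    ppas_a: pd.DataFrame,
    ppas_b: pd.DataFrame,
    concurrent_threshold_h: float = 1.0,
    lag_bins: tuple[float, ...] = DEFAULT_LAG_BINS,
    max_lag_h: float | None = None,
    compute_area: bool = True,
) -> pd.DataFrame:
    """All intersecting PPA pairs of a dyad, classified by lag.

    Returns one row per intersection event with the two ellipses' time
    intervals, movement descriptors (speed, heading) of the generating
    segments, the absolute start-time lag, who moved first, the
    concurrent/delayed kind and the delayed-lag bin.
    """
    import shapely

    cols = [
        "i_a", "i_b", "t_start_a", "t_end_a", "t_start_b", "t_end_b",
        "lag_h", "kind", "bin_h", "who_first", "area_m2",
        "heading_a", "heading_b", "heading_valid", "speed_a", "speed_b",
    ]
    if max_lag_h is None:
        max_lag_h = max(lag_bins) + concurrent_threshold_h if lag_bins else np.inf
    pairs = candidate_pairs(ppas_a, ppas_b, max_lag_h)
    if len(pairs) == 0:
        return pd.DataFrame(columns=cols)
    ia, ib = pairs[:, 0], pairs[:, 1]

    # cheap vectorized separation bound before exact GEOS tests
    dx = ppas_a["cx"].to_numpy()[ia] - ppas_b["cx"].to_numpy()[ib]
    dy = ppas_a["cy"].to_numpy()[ia] - ppas_b["cy"].to_numpy()[ib]
    close = np.hypot(dx, dy) <= (
        ppas_a["a"].to_numpy()[ia] + ppas_b["a"].to_numpy()[ib]
    )
    ia, ib = ia[close], ib[close]
    if ia.size == 0:
        return pd.DataFrame(columns=cols)

    geoms_a = ppas_a["geometry"].to_numpy()[ia]
    geoms_b = ppas_b["geometry"].to_numpy()[ib]
    hit = shapely.intersects(geoms_a, geoms_b)
    ia, ib = ia[hit], ib[hit]
    if ia.size == 0:
        return pd.DataFrame(columns=cols)
    if compute_area:
        area = shapely.area(shapely.intersection(geoms_a[hit], geoms_b[hit]))
    else:
        area = np.full(ia.size, np.nan)

    tsa = pd.DatetimeIndex(ppas_a["t_start"]).asi8
    tsb = pd.DatetimeIndex(ppas_b["t_start"]).asi8
    lag = np.abs(tsa[ia] - tsb[ib]) / 3.6e12
    kinds = np.where(lag <= concurrent_threshold_h, "concurrent", "delayed")
    bins_sorted = np.asarray(sorted(lag_bins), dtype=float)
    if bins_sorted.size:
        bin_idx = np.searchsorted(bins_sorted, lag, side="right") - 1
        bin_h = np.where(bin_idx >= 0, bins_sorted[np.maximum(bin_idx, 0)], 0.0)
    else:
        bin_h = np.zeros(lag.size)
    bin_h = np.where(kinds == "concurrent", np.nan, bin_h)
    who_first = np.where(
        tsa[ia] < tsb[ib], "a", np.where(tsb[ib] < tsa[ia], "b", "tie")
    )

    df = pd.DataFrame(
        {
            "i_a": ia,
            "i_b": ib,
            "t_start_a": ppas_a["t_start"].to_numpy()[ia],
            "t_end_a": ppas_a["t_end"].to_numpy()[ia],
            "t_start_b": ppas_b["t_start"].to_numpy()[ib],
            "t_end_b": ppas_b["t_end"].to_numpy()[ib],
            "lag_h": lag,
            "kind": kinds,
            "bin_h": bin_h,
            "who_first": who_first,
            "area_m2": area,
            "heading_a": ppas_a["heading"].to_numpy()[ia],
            "heading_b": ppas_b["heading"].to_numpy()[ib],
            "heading_valid": (
                ppas_a["heading_valid"].to_numpy()[ia]
                & ppas_b["heading_valid"].to_numpy()[ib]
            ),
            "speed_a": ppas_a["speed"].to_numpy()[ia],
            "speed_b": ppas_b["speed"].to_numpy()[ib],
        },
        columns=cols,
    )
    return df.sort_values(["t_start_a", "t_start_b"], kind="mergesort").reset_index(
        drop=True
    )


def trace_segments(
    events: pd.DataFrame, sampling_interval_h: float = 1.0
) -> pd.DataFrame:
    """Partition events into maximal continuous interaction segments.

    Each event spans the union of its two PPAs' time intervals; events
    whose spans overlap or abut within one sampling interval belong to
    the same segment. Per segment, duration is the difference between
    the latest end and the earliest start over all member PPAs.

    Returns one row per segment: t_min, t_max, duration_h, n_events,
    and the member event indices.
    """
    cols = ["t_min", "t_max", "duration_h", "n_events", "event_idx"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)
    start = np.minimum(events["t_start_a"].to_numpy(), events["t_start_b"].to_numpy())
    end = np.maximum(events["t_end_a"].to_numpy(), events["t_end_b"].to_numpy())
    order = np.argsort(start, kind="stable")
    tol = sampling_interval_h * HOUR

    segments = []
    cur: list[int] = []
    cur_end = None
    for idx in order:
        if cur and start[idx] > cur_end + tol:
            segments.append(cur)
            cur = []
            cur_end = None
        cur.append(int(idx))
        cur_end = end[idx] if cur_end is None else max(cur_end, end[idx])
    if cur:
        segments.append(cur)

    rows = []
    for members in segments:
        t_min = min(start[m] for m in members)
        t_max = max(end[m] for m in members)
        rows.append(
            {
                "t_min": pd.Timestamp(t_min),
                "t_max": pd.Timestamp(t_max),
                "duration_h": float((t_max - t_min) / HOUR),
                "n_events": len(members),
                "event_idx": members,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def _month(ts: pd.Timestamp) -> pd.Period:
    """Calendar month in the timestamp's own (wall-clock) timezone."""
    if ts.tz is not None:
        ts = ts.tz_localize(None)
    return ts.to_period("M")


def _split_by_month(t0: pd.Timestamp, t1: pd.Timestamp) -> list[tuple[pd.Period, float]]:
    """Hours of [t0, t1] falling in each calendar month."""
    out = []
    cur = t0
    while cur < t1:
        month = _month(cur)
        month_end = (month + 1).to_timestamp()
        if cur.tz is not None:
            month_end = month_end.tz_localize(cur.tz)
        nxt = min(t1, month_end)
        out.append((month, float((nxt - cur) / pd.Timedelta(hours=1))))
        cur = nxt
    if not out:  # zero-duration segment still counts in its month
        out.append((_month(t0), 0.0))
    return out


def monthly_summary(
    segments: pd.DataFrame,
    delayed_events: pd.DataFrame,
    first_per_day: bool = False,
) -> pd.DataFrame:
    """Per-calendar-month interaction frequencies and durations.

    Concurrent segments contribute a count (frequency, in the month the
    segment starts) and their duration in hours, split exactly at month
    boundaries. Delayed events are counted per month per lag bin;
    ``first_per_day`` keeps only the first delayed event per calendar
    day per bin before counting.

    Returns a long-format table: month (Period), kind ('concurrent' or
    'delayed'), bin_h, frequency, duration_h.
    """
    rows: dict[tuple, dict] = {}

    def bucket(month, kind, bin_h):
        key = (month, kind, None if bin_h != bin_h else bin_h)  # NaN-safe key
        if key not in rows:
            rows[key] = {
                "month": month, "kind": kind, "bin_h": bin_h,
                "frequency": 0, "duration_h": 0.0,
            }
        return rows[key]

    for _, seg in segments.iterrows():
        t0 = pd.Timestamp(seg["t_min"])
        bucket(_month(t0), "concurrent", float("nan"))["frequency"] += 1
        for month, hours in _split_by_month(t0, pd.Timestamp(seg["t_max"])):
            bucket(month, "concurrent", float("nan"))["duration_h"] += hours

    dev = delayed_events
    if len(dev):
        t_min = np.minimum(dev["t_start_a"].to_numpy(), dev["t_start_b"].to_numpy())
        dev = dev.assign(_t=t_min)
        if first_per_day:
            day = pd.DatetimeIndex(dev["_t"]).floor("D")
            dev = dev.assign(_day=day).drop_duplicates(subset=["_day", "bin_h"])
        for _, ev in dev.iterrows():
            bucket(_month(pd.Timestamp(ev["_t"])), "delayed", float(ev["bin_h"]))[
                "frequency"
            ] += 1

    out = pd.DataFrame(
        rows.values(),
        columns=["month", "kind", "bin_h", "frequency", "duration_h"],
    )
    if len(out):
        out = out.sort_values(["month", "kind", "bin_h"]).reset_index(drop=True)
    return out


@dataclass
class DyadResult:
    """Full interaction analysis of one dyad."""

    id_a: str
    id_b: str
    events: pd.DataFrame
    concurrent_segments: pd.DataFrame
    delayed_events: pd.DataFrame = field(default_factory=pd.DataFrame)
    monthly: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def dyad(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    @property
    def total_concurrent_duration_h(self) -> float:
        if len(self.concurrent_segments) == 0:
            return 0.0
        return float(self.concurrent_segments["duration_h"].sum())


def analyze_dyad(
    ppas_a: pd.DataFrame,
    ppas_b: pd.DataFrame,
    id_a: str = "a",
    id_b: str = "b",
    concurrent_threshold_h: float = 1.0,
    lag_bins: tuple[float, ...] = DEFAULT_LAG_BINS,
    sampling_interval_h: float = 1.0,
    first_per_day: bool = False,
) -> DyadResult:
    """Events -> lag classification -> segment tracing -> monthly table."""
    events = find_events(ppas_a, ppas_b, concurrent_threshold_h, lag_bins)
    concurrent = events[events["kind"] == "concurrent"].reset_index(drop=True)
    delayed = events[events["kind"] == "delayed"].reset_index(drop=True)
    segments = trace_segments(concurrent, sampling_interval_h)
    monthly = monthly_summary(segments, delayed, first_per_day)
    return DyadResult(id_a, id_b, events, segments, delayed, monthly)
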