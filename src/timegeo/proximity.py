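"""Proximity-based contact detection — the comparison baseline.

The conventional approach declares a contact whenever two individuals'
fixes fall within a spatial buffer (meters) of each other inside a time
window (minutes). It depends on simultaneous, regular fixes: with a
zero time window and desynchronized collars it detects nothing, which
is the failure mode the PPA-intersection method is designed to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

HOUR = pd.Timedelta(hours=1)

#: the standard evaluation grid: buffers (m) x time windows (min)
DEFAULT_BUFFERS_M = (200.0, 500.0, 1000.0, 2000.0)
DEFAULT_WINDOWS_MIN = (0.0, 30.0, 60.0)


@dataclass
class ProximityParams:
    """Spatial buffer delta (m) and time window tau (min)."""

    buffer_m: float = 200.0
    window_min: float = 0.0

    def __post_init__(self) -> None:
        if self.buffer_m <= 0:
            raise ValueError("buffer must be > 0")
        if self.window_min < 0:
            raise ValueError("time window must be >= 0")


def proximity_events(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    params: ProximityParams,
) -> pd.DataFrame:
    """Fix pairs within the buffer and time window.

    A contact is every (fix_a, fix_b) pair with
    ``|t_a - t_b| <= tau`` and Euclidean distance ``<= delta``;
    ``tau = 0`` requires exactly equal timestamps. Returns a table with
    the pair times, the contact time (midpoint) and the distance.
    """
    ta = track_a["t"].to_numpy()
    tb = track_b["t"].to_numpy()
    xa = track_a[["x", "y"]].to_numpy(dtype=float)
    xb = track_b[["x", "y"]].to_numpy(dtype=float)
    tol = pd.Timedelta(minutes=params.window_min)

    rows = []
    # two-pointer sweep over the time-sorted tracks
    j_lo = 0
    for i in range(len(ta)):
        while j_lo < len(tb) and tb[j_lo] < ta[i] - tol:
            j_lo += 1
        j = j_lo
        while j < len(tb) and tb[j] <= ta[i] + tol:
            d = float(np.hypot(*(xa[i] - xb[j])))
            if d <= params.buffer_m:
                rows.append(
                    {
                        "t_a": ta[i],
                        "t_b": tb[j],
                        "t": ta[i] + (tb[j] - ta[i]) / 2,
                        "dist_m": d,
                    }
                )
            j += 1
    return pd.DataFrame(rows, columns=["t_a", "t_b", "t", "dist_m"])


def proximity_segments(
    contacts: pd.DataFrame, sampling_interval_h: float = 1.0
) -> pd.DataFrame:
    """Chain time-adjacent contacts into runs and measure durations.

    Contacts within one sampling interval of the previous contact in
    the run belong to the same run; a run's duration is last minus
    first contact time (a single isolated contact is an encounter of
    duration 0).
    """
    cols = ["t_min", "t_max", "duration_h", "n_contacts"]
    if len(contacts) == 0:
        return pd.DataFrame(columns=cols)
    t = np.sort(contacts["t"].to_numpy())
    tol = pd.Timedelta(hours=sampling_interval_h)
    rows = []
    run_start = t[0]
    prev = t[0]
    n = 1
    for ti in t[1:]:
        if ti - prev > tol:
            rows.append(
                {
                    "t_min": run_start,
                    "t_max": prev,
                    "duration_h": float((prev - run_start) / HOUR),
                    "n_contacts": n,
                }
            )
            run_start = ti
            n = 0
        prev = ti
        n += 1
    rows.append(
        {
            "t_min": run_start,
            "t_max": prev,
            "duration_h": float((prev - run_start) / HOUR),
            "n_contacts": n,
        }
    )
    return pd.DataFrame(rows, columns=cols)


def compare_methods(
    durations_ppa, durations_proximity
) -> dict:
    """Mann-Whitney U comparison of two duration distributions.

    Two-sided test with tie correction; when either sample is empty a
    degenerate report is returned instead of a p-value.
    """
    a = np.asarray(list(durations_ppa), dtype=float)
    b = np.asarray(list(durations_proximity), dtype=float)
    report = {
        "n_ppa": int(a.size),
        "n_proximity": int(b.size),
        "median_ppa": float(np.median(a)) if a.size else None,
        "median_proximity": float(np.median(b)) if b.size else None,
    }
    if a.size == 0 or b.size == 0:
        report.update(U=None, p=None, note="no interactions detected in a sample")
        return report
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    report.update(U=float(res.statistic), p=float(res.pvalue), note="")
    return report


def sweep(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    buffers_m=DEFAULT_BUFFERS_M,
    windows_min=DEFAULT_WINDOWS_MIN,
    sampling_interval_h: float = 1.0,
) -> pd.DataFrame:
    """Contact counts and duration lists over the (delta, tau) grid.

    Long-format output with one row per grid cell, suitable for box
    plots of duration against window size at each buffer.
    """
    rows = []
    for delta in buffers_m:
        for tau in windows_min:
            contacts = proximity_events(
                track_a, track_b, ProximityParams(delta, tau)
            )
            runs = proximity_segments(contacts, sampling_interval_h)
            rows.append(
                {
                    "delta_m": delta,
                    "tau_min": tau,
                    "n_contacts": len(contacts),
                    "n_runs": len(runs),
                    "durations_h": list(runs["duration_h"]) if len(runs) else [],
                }
            )
    return pd.DataFrame(rows)
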