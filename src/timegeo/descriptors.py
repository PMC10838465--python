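"""Movement-parameter descriptors at intersecting PPAs.

At every intersection event the two generating segments carry a heading
and a speed; the absolute circular heading difference (0-180 deg) and
absolute speed difference summarize how aligned the two movements were.
Kernel densities of these differences separate behavioral signatures:
co-movement ("following") concentrates near zero heading difference and
similar speed, head-on meetings ("encounter") concentrate above 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


def circular_difference(h1, h2) -> np.ndarray:
    """Absolute heading difference on the circle, in [0, 180]."""
    d = np.abs(np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def describe_events(events: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-event heading and speed differences.

    Events whose either segment has a flagged (zero-displacement)
    heading are excluded; the count of exclusions is returned alongside
    the descriptor table (columns d_heading, d_speed, lag_h, kind).
    """
    if len(events) == 0:
        return (
            pd.DataFrame(columns=["d_heading", "d_speed", "lag_h", "kind", "bin_h"]),
            0,
        )
    valid = events["heading_valid"].to_numpy(dtype=bool)
    ev = events.loc[valid]
    out = pd.DataFrame(
        {
            "d_heading": circular_difference(ev["heading_a"], ev["heading_b"]),
            "d_speed": np.abs(
                ev["speed_a"].to_numpy(dtype=float)
                - ev["speed_b"].to_numpy(dtype=float)
            ),
            "lag_h": ev["lag_h"].to_numpy(dtype=float),
            "kind": ev["kind"].to_numpy(),
            "bin_h": ev["bin_h"].to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out, int((~valid).sum())


def kde_profile(
    values,
    kind: str = "direction",
    bandwidth: str | float = "scott",
    grid_size: int = 256,
) -> dict:
    """Gaussian kernel density over a descriptor sample.

    Direction support is clipped to [0, 180] degrees; speed support
    spans [0, max]. Returns the evaluation grid, densities and the
    sample size n (fewer than 2 values yields a report without a
    density curve).
    """
    v = np.asarray(list(values), dtype=float)
    n = v.size
    if n < 2 or np.allclose(v, v[0]):
        return {"kind": kind, "n": n, "grid": None, "density": None}
    kde = gaussian_kde(v, bw_method=bandwidth)
    if kind == "direction":
        grid = np.linspace(0.0, 180.0, grid_size)
    else:
        grid = np.linspace(0.0, float(v.max()) * 1.1 + 1e-9, grid_size)
    return {"kind": kind, "n": n, "grid": grid, "density": kde(grid)}


@dataclass
class SignatureThresholds:
    """Heuristic cutoffs for the advisory pattern labels."""

    following_max_heading_deg: float = 45.0
    following_min_duration_intervals: float = 3.0
    avoidance_frequency_quantile: float = 0.25


def segment_signature(
    segment: pd.Series,
    descriptors: pd.DataFrame,
    kind: str = "concurrent",
    sampling_interval_h: float = 1.0,
    thresholds: SignatureThresholds | None = None,
) -> dict:
    """Quantitative signature of one interaction segment.

    Always emits the mean heading/speed differences, duration, kind and
    lag. A rule-based label (following / encounter / latency) is
    attached as an explicitly heuristic aid: prolonged concurrent runs
    with near-parallel headings read as following, short concurrent
    runs as encounters, delayed events as latency. Avoidance is a
    dyad-level judgment (low concurrent frequency) and is not labeled
    here.
    """
    thresholds = thresholds or SignatureThresholds()
    mean_dh = float(descriptors["d_heading"].mean()) if len(descriptors) else np.nan
    mean_dv = float(descriptors["d_speed"].mean()) if len(descriptors) else np.nan
    duration = float(segment.get("duration_h", np.nan))
    mean_lag = float(descriptors["lag_h"].mean()) if len(descriptors) else np.nan

    label = None
    if kind == "delayed":
        label = "latency"
    elif kind == "concurrent":
        long_run = (
            duration
            >= thresholds.following_min_duration_intervals * sampling_interval_h
        )
        if long_run and mean_dh < thresholds.following_max_heading_deg:
            label = "following"
        elif not long_run:
            label = "encounter"
    return {
        "mean_d_heading": mean_dh,
        "mean_d_speed": mean_dv,
        "duration_h": duration,
        "kind": kind,
        "mean_lag_h": mean_lag,
        "label": label,
        "label_is_heuristic": True,
    }


def dyad_avoidance_flag(
    concurrent_frequency: float,
    reference_frequencies,
    thresholds: SignatureThresholds | None = None,
) -> bool:
    """Dyad-level avoidance: concurrent frequency below a quantile of peers."""
    thresholds = thresholds or SignatureThresholds()
    ref = np.asarray(list(reference_frequencies), dtype=float)
    if ref.size == 0:
        return False
    return concurrent_frequency <= np.quantile(
        ref, thresholds.avoidance_frequency_quantile
    )
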