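"""Potential path areas (PPAs) with EWMA speed budgets.

Between two consecutive fixes, the set of locations an animal moving at
most at speed ``v_max`` can have visited is an ellipse with the two
fixes at its foci and major axis ``v_max * dt``. The speed budget for
each segment is an exponentially weighted moving average (EWMA) of the
recent observed speeds, inflated by a multiplicative error term to
allow bursts above the smoothed average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

DEFAULT_VERTICES = 100


@dataclass
class EWMAParams:
    """EWMA speed-smoothing parameters.

    lam
        Smoothing constant in (0, 1]. ``lam = 1`` uses the current
        segment speed unsmoothed; smaller values weight more history.
    n
        Window length: number of past speeds entering the sum.
    epsilon
        Multiplicative error term (>= 1) inflating the smoothed speed
        into a maximum-speed budget; default 1.25 allows 25% headroom
        over the smoothed average.
    renormalize
        If True, rescale the truncated weight sum to 1 at the head of a
        track (the plain truncated sum is the default).
    """

    lam: float = 0.5
    n: int = 10
    epsilon: float = 1.25
    renormalize: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"lambda must be in (0, 1], got {self.lam}")
        if self.n < 1:
            raise ValueError("window length n must be >= 1")
        if self.epsilon < 1.0:
            raise ValueError("epsilon must be >= 1")


def ewma_max_speed(
    speeds: np.ndarray, params: EWMAParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment maximum-speed budgets from time-ordered speeds.

    The smoothed speed at segment i is
    ``s_i = sum_{k=0}^{n-1} lam * (1-lam)^k * v_{i-k}`` (just ``v_i``
    when ``lam = 1``), truncated to the available history at the head
    of the track. The budget is ``epsilon * s_i``, floored at the
    observed speed ``v_i`` so the ellipse can always contain its own
    chord; the returned boolean array flags segments where the floor
    was active.

    Returns (v_max, floored_flag).
    """
    params = params or EWMAParams()
    v = np.asarray(speeds, dtype=float)
    if v.ndim != 1:
        raise ValueError("speeds must be 1-D")
    if not np.isfinite(v).all():
        raise ValueError("non-finite speed encountered")

    if params.lam == 1.0:
        s = v.copy()
    else:
        m = v.size
        k = np.arange(params.n)
        w = params.lam * (1.0 - params.lam) ** k
        s = np.empty(m)
        for i in range(m):
            take = min(params.n, i + 1)
            wi = w[:take]
            if params.renormalize:
                wi = wi / wi.sum()
            s[i] = np.dot(wi, v[i::-1][:take])
    raw = params.epsilon * s
    v_max = np.maximum(raw, v)
    return v_max, raw < v


def build_ppas(
    segments: pd.DataFrame,
    v_max: np.ndarray,
    n_vertices: int = DEFAULT_VERTICES,
) -> pd.DataFrame:
    """Construct one PPA ellipse per movement segment.

    Foci are the segment's two fixes; the semi-major axis is
    ``a = v_max * dt / 2`` and the half focal distance ``c = dist / 2``.
    The boundary is a polygon with ``n_vertices`` vertices at equal
    parametric angles. When ``a == c`` (budget exactly the observed
    speed) the ellipse degenerates to the chord and is kept as a
    flagged zero-area line geometry.

    Returns a DataFrame with geometry and ellipse parameters, aligned
    row-for-row with ``segments``.
    """
    v_max = np.asarray(v_max, dtype=float)
    if len(v_max) != len(segments):
        raise ValueError("v_max length must match segments")
    dt = segments["dt_h"].to_numpy()
    dist = segments["dist_m"].to_numpy()
    a = v_max * dt / 2.0
    c = dist / 2.0
    if np.any(a < c - 1e-9):
        raise ValueError("v_max * dt < dist: infeasible ellipse")
    a = np.maximum(a, c)
    b = np.sqrt(np.maximum(a**2 - c**2, 0.0))
    cx = (segments["x1"].to_numpy() + segments["x2"].to_numpy()) / 2.0
    cy = (segments["y1"].to_numpy() + segments["y2"].to_numpy()) / 2.0
    theta = np.arctan2(
        segments["y2"].to_numpy() - segments["y1"].to_numpy(),
        segments["x2"].to_numpy() - segments["x1"].to_numpy(),
    )

    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    cos_phi, sin_phi = np.cos(phi), np.sin(phi)
    geoms = []
    degenerate = b < 1e-9
    for i in range(len(a)):
        if degenerate[i]:
            if c[i] < 1e-9:
                # zero displacement, zero budget: a point-like chord
                geoms.append(
                    LineString([(cx[i], cy[i]), (cx[i] + 1e-9, cy[i])])
                )
            else:
                geoms.append(
                    LineString(
                        [
                            (segments["x1"].iloc[i], segments["y1"].iloc[i]),
                            (segments["x2"].iloc[i], segments["y2"].iloc[i]),
                        ]
                    )
                )
            continue
        ex = a[i] * cos_phi
        ey = b[i] * sin_phi
        ct, st = np.cos(theta[i]), np.sin(theta[i])
        px = cx[i] + ex * ct - ey * st
        py = cy[i] + ex * st + ey * ct
        geoms.append(Polygon(np.column_stack([px, py])))

    out = pd.DataFrame(
        {
            "t_start": segments["t_start"].to_numpy(),
            "t_end": segments["t_end"].to_numpy(),
            "dt_h": dt,
            "a": a,
            "b": b,
            "c": c,
            "cx": cx,
            "cy": cy,
            "orientation": np.degrees(theta),
            "v_max": v_max,
            "speed": segments["speed"].to_numpy(),
            "heading": segments["heading"].to_numpy(),
            "heading_valid": segments["heading_valid"].to_numpy(),
            "degenerate": degenerate,
        }
    )
    out["geometry"] = geoms
    return out


def filter_gap_ppas(
    ppas: pd.DataFrame,
    stats: tuple[float, float],
    k: float = 3.0,
    rule: str = "mean_plus_k_sd",
) -> tuple[pd.DataFrame, int]:
    """Drop PPAs spanning sampling gaps.

    Oversized ellipses produced by missed fixes create spurious
    intersections, so any PPA whose time interval exceeds the gap
    threshold is removed. The default threshold is
    ``mean_dt + k * sd_dt`` (k = 3); ``rule="k_sd"`` uses the literal
    ``k * sd_dt`` reading instead.

    Returns (retained PPAs, number dropped).
    """
    mean_dt, sd_dt = stats
    if rule == "mean_plus_k_sd":
        threshold = mean_dt + k * sd_dt
    elif rule == "k_sd":
        threshold = k * sd_dt
    else:
        raise ValueError(f"unknown gap rule {rule!r}")
    keep = ppas["dt_h"].to_numpy() <= threshold + 1e-12
    dropped = int((~keep).sum())
    return ppas.loc[keep].reset_index(drop=True), dropped


def ppas_for_track(
    track: pd.DataFrame,
    params: EWMAParams | None = None,
    gap_k: float = 3.0,
    gap_rule: str = "mean_plus_k_sd",
    n_vertices: int = DEFAULT_VERTICES,
) -> tuple[pd.DataFrame, int]:
    """Segments -> EWMA budgets -> ellipses -> gap filter, for one track."""
    from .io import build_segments, interval_stats

    segments = build_segments(track)
    v_max, floored = ewma_max_speed(segments["speed"].to_numpy(), params)
    ppas = build_ppas(segments, v_max, n_vertices)
    ppas["v_max_floored"] = floored
    return filter_gap_ppas(ppas, interval_stats(track), gap_k, gap_rule)


def export_ppas_csv(ppas: pd.DataFrame, path, individual_id: str = "") -> None:
    cols = [
        "t_start", "t_end", "a", "b", "cx", "cy",
        "orientation", "v_max", "degenerate",
    ]
    out = ppas[cols].copy()
    if individual_id:
        out.insert(0, "id", individual_id)
    out.to_csv(path, index=False)
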