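import numpy as np
import pandas as pd
import pytest

from timegeo.io import tracks_from_frame


def make_track(times, xy, tz="UTC"):
    """Fix table (t, x, y) from timestamp strings and coordinate pairs."""
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "t": pd.to_datetime(list(times), utc=True, format="mixed"),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )


def hourly_track(n, xy, start="2020-06-01T00:00:00"):
    t0 = pd.Timestamp(start, tz="UTC")
    times = [t0 + pd.Timedelta(hours=i) for i in range(n)]
    return make_track([str(t) for t in times], xy)


def make_event(t_start_a, t_end_a, t_start_b, t_end_b, **kw):
    """One intersection-event row with sensible descriptor defaults."""
    row = {
        "i_a": kw.get("i_a", 0),
        "i_b": kw.get("i_b", 0),
        "t_start_a": pd.Timestamp(t_start_a, tz="UTC"),
        "t_end_a": pd.Timestamp(t_end_a, tz="UTC"),
        "t_start_b": pd.Timestamp(t_start_b, tz="UTC"),
        "t_end_b": pd.Timestamp(t_end_b, tz="UTC"),
        "lag_h": kw.get("lag_h", 0.0),
        "kind": kw.get("kind", "concurrent"),
        "bin_h": kw.get("bin_h", float("nan")),
        "who_first": kw.get("who_first", "tie"),
        "area_m2": kw.get("area_m2", 1.0),
        "heading_a": kw.get("heading_a", 0.0),
        "heading_b": kw.get("heading_b", 0.0),
        "heading_valid": kw.get("heading_valid", True),
        "speed_a": kw.get("speed_a", 100.0),
        "speed_b": kw.get("speed_b", 100.0),
    }
    return row


def events_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def straight_track():
    """Five hourly fixes marching due north at 1000 m/h."""
    return hourly_track(5, [(0, 1000 * i) for i in range(5)])


@pytest.fixture
def two_individual_csv(tmp_path):
    """Interleaved two-individual lon/lat telemetry CSV."""
    rows = []
    t0 = pd.Timestamp("2020-06-01T00:00:00", tz="UTC")
    for i in range(4):
        rows.append(("amy", str(t0 + pd.Timedelta(hours=i)), 99.1 + 0.001 * i, 15.5))
        rows.append(("ben", str(t0 + pd.Timedelta(hours=i)), 99.2, 15.6 + 0.001 * i))
    df = pd.DataFrame(rows, columns=["id", "t", "lon", "lat"])
    df = df.sample(frac=1.0, random_state=0)  # shuffle row order
    path = tmp_path / "two.csv"
    df.to_csv(path, index=False)
    return path


def random_ppas(rng, n, span_m=10000.0, t0="2020-06-01", a_range=(300.0, 1500.0)):
    """Random PPA table (geometry + centroid/axis columns) for testing."""
    from timegeo.io import build_segments
    from timegeo.ppa import build_ppas

    start = pd.Timestamp(t0, tz="UTC")
    xs = rng.uniform(0, span_m, n + 1)
    ys = rng.uniform(0, span_m, n + 1)
    times = [start + pd.Timedelta(hours=i) for i in range(n + 1)]
    track = pd.DataFrame({"t": times, "x": xs, "y": ys})
    seg = build_segments(track)
    # budgets somewhat above the observed speed give non-degenerate ellipses
    v_max = seg["speed"].to_numpy() * rng.uniform(1.05, 1.6, n)
    v_max = np.maximum(v_max, a_range[0] * 2)
    return build_ppas(seg, v_max)
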