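import numpy as np
import pandas as pd
import pytest
import shapely

from timegeo.interaction import (
    DEFAULT_LAG_BINS,
    analyze_dyad,
    candidate_pairs,
    classify_lag,
    ellipse_intersects,
    find_events,
    monthly_summary,
    trace_segments,
)

from conftest import events_frame, make_event, random_ppas


def brute_force_intersections(ppas_a, ppas_b):
    """All-pairs shapely intersection oracle, no spatial index."""
    out = set()
    for i, ga in enumerate(ppas_a["geometry"]):
        for j, gb in enumerate(ppas_b["geometry"]):
            if ga.intersects(gb):
                out.add((i, j))
    return out


def mc_ellipse_overlap(row_a, row_b, n_samples, rng):
    """Monte-Carlo membership oracle on the focal-distance definition.

    A point is inside an ellipse iff the sum of its distances to the
    two foci is at most the major axis 2a. Returns the estimated
    overlap area and its standard error.
    """

    def foci(row):
        th = np.radians(row["orientation"])
        c = row["c"]
        f = np.array([np.cos(th), np.sin(th)]) * c
        ctr = np.array([row["cx"], row["cy"]])
        return ctr - f, ctr + f, 2.0 * row["a"]

    f1a, f2a, major_a = foci(row_a)
    f1b, f2b, major_b = foci(row_b)
    lo = np.minimum.reduce([f1a, f2a, f1b, f2b]) - max(row_a["a"], row_b["a"])
    hi = np.maximum.reduce([f1a, f2a, f1b, f2b]) + max(row_a["a"], row_b["a"])
    pts = rng.uniform(lo, hi, (n_samples, 2))
    box_area = np.prod(hi - lo)

    def inside(pts, f1, f2, major):
        return (
            np.hypot(*(pts - f1).T) + np.hypot(*(pts - f2).T) <= major
        )

    hits = inside(pts, f1a, f2a, major_a) & inside(pts, f1b, f2b, major_b)
    p = hits.mean()
    area = box_area * p
    se = box_area * np.sqrt(p * (1 - p) / n_samples)
    return area, se


class TestCandidatePairs:
    def test_disjoint_tracking_periods_empty(self):
        rng = np.random.default_rng(0)
        pa = random_ppas(rng, 20, t0="2020-06-01")
        pb = random_ppas(rng, 20, t0="2021-06-01")
        assert len(candidate_pairs(pa, pb, max_lag_h=0.0)) == 0

    def test_filters_disabled_all_pairs(self):
        rng = np.random.default_rng(1)
        pa = random_ppas(rng, 10)
        pb = random_ppas(rng, 12)
        pairs = candidate_pairs(pa, pb, max_lag_h=np.inf)
        # centroid radius still applies; force every pair inside it
        assert len(pairs) <= 10 * 12
        small = random_ppas(rng, 5, span_m=100.0)
        pairs = candidate_pairs(small, small, max_lag_h=np.inf)
        assert len(pairs) == 25

    def test_superset_of_brute_force(self):
        rng = np.random.default_rng(2)
        pa = random_ppas(rng, 100, span_m=6000.0)
        pb = random_ppas(rng, 100, span_m=6000.0)
        cand = {tuple(p) for p in candidate_pairs(pa, pb, np.inf)}
        assert brute_force_intersections(pa, pb) <= cand


class TestEllipseIntersects:
    def test_identical_ellipses(self):
        rng = np.random.default_rng(3)
        p = random_ppas(rng, 1)
        hit, area = ellipse_intersects(p["geometry"][0], p["geometry"][0])
        assert hit
        assert area == pytest.approx(p["geometry"][0].area)

    def test_far_separation(self):
        rng = np.random.default_rng(4)
        pa = random_ppas(rng, 1, span_m=100.0)
        pb = random_ppas(rng, 1, span_m=100.0)
        moved = shapely.affinity.translate(pb["geometry"][0], xoff=1e6)
        hit, area = ellipse_intersects(pa["geometry"][0], moved)
        assert not hit and area == 0.0

    def test_overlap_area_matches_monte_carlo(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 10:
            pa = random_ppas(rng, 1, span_m=2000.0)
            pb = random_ppas(rng, 1, span_m=2000.0)
            hit, area = ellipse_intersects(pa["geometry"][0], pb["geometry"][0])
            if not hit or area == 0.0:
                continue
            mc_area, se = mc_ellipse_overlap(pa.iloc[0], pb.iloc[0], 100_000, rng)
            assert abs(area - mc_area) < 5 * se + 1e-9
            checked += 1


class TestClassifyLag:
    @pytest.mark.parametrize(
        "lag,expected_kind,expected_bin",
        [
            (0.5, "concurrent", None),
            (1.0, "concurrent", None),  # threshold is inclusive
            (1.01, "delayed", 0.0),     # below the smallest bin
            (30.0, "delayed", 24.0),
            (24.0, "delayed", 24.0),    # closed lower bound
            (200.0, "delayed", 168.0),
            (600.0, "delayed", 504.0),
        ],
    )
    def test_threshold_and_bins(self, lag, expected_kind, expected_bin):
        kind, bin_h = classify_lag(lag, 1.0, DEFAULT_LAG_BINS)
        assert kind == expected_kind
        if expected_bin is None:
            assert np.isnan(bin_h)
        else:
            assert bin_h == expected_bin

    def test_two_bin_example(self):
        kind, bin_h = classify_lag(30.0, 1.0, (24.0, 168.0))
        assert (kind, bin_h) == ("delayed", 24.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_lag(0.5, -1.0)


class TestTraceSegments:
    def test_single_event_duration(self):
        ev = events_frame(
            [make_event("2020-06-01T09:00", "2020-06-01T10:00",
                        "2020-06-01T09:00", "2020-06-01T10:00")]
        )
        seg = trace_segments(ev)
        assert len(seg) == 1
        assert seg["duration_h"].iloc[0] == 1.0

    def test_chained_events_merge(self):
        ev = events_frame(
            [
                make_event("2020-06-01T09:00", "2020-06-01T10:00",
                           "2020-06-01T09:00", "2020-06-01T10:00"),
                make_event("2020-06-01T10:00", "2020-06-01T11:00",
                           "2020-06-01T09:00", "2020-06-01T10:00"),
                make_event("2020-06-01T11:00", "2020-06-01T12:00",
                           "2020-06-01T11:00", "2020-06-01T12:00"),
            ]
        )
        seg = trace_segments(ev)
        assert len(seg) == 1
        assert seg["duration_h"].iloc[0] == 3.0
        assert seg["n_events"].iloc[0] == 3

    def test_gap_splits_runs(self):
        ev = events_frame(
            [
                make_event("2020-06-01T09:00", "2020-06-01T10:00",
                           "2020-06-01T09:00", "2020-06-01T10:00"),
                make_event("2020-06-01T15:00", "2020-06-01T16:00",
                           "2020-06-01T15:00", "2020-06-01T16:00"),
            ]
        )
        seg = trace_segments(ev)
        assert len(seg) == 2

    def test_empty_input(self):
        assert len(trace_segments(events_frame([])[0:0])) == 0

    def test_duration_is_max_end_minus_min_start(self):
        # events deliberately out of order with nested intervals
        ev = events_frame(
            [
                make_event("2020-06-01T10:00", "2020-06-01T11:00",
                           "2020-06-01T09:30", "2020-06-01T12:30"),
                make_event("2020-06-01T09:00", "2020-06-01T10:00",
                           "2020-06-01T09:00", "2020-06-01T10:00"),
            ]
        )
        seg = trace_segments(ev)
        assert len(seg) == 1
        assert seg["duration_h"].iloc[0] == pytest.approx(3.5)


class TestMonthlySummary:
    def test_empty(self):
        ev = events_frame([])[0:0]
        out = monthly_summary(trace_segments(ev), ev)
        assert len(out) == 0

    def test_single_segment_inside_month(self):
        ev = events_frame(
            [make_event("2020-06-10T09:00", "2020-06-10T12:00",
                        "2020-06-10T09:00", "2020-06-10T12:00")]
        )
        out = monthly_summary(trace_segments(ev), ev[0:0])
        conc = out[out["kind"] == "concurrent"]
        assert len(conc) == 1
        assert conc["frequency"].iloc[0] == 1
        assert conc["duration_h"].iloc[0] == 3.0

    def test_month_boundary_split(self):
        ev = events_frame(
            [make_event("2020-05-31T23:00", "2020-06-01T02:00",
                        "2020-05-31T23:00", "2020-06-01T02:00")]
        )
        out = monthly_summary(trace_segments(ev), ev[0:0])
        conc = out[out["kind"] == "concurrent"].set_index(
            out[out["kind"] == "concurrent"]["month"].astype(str)
        )
        assert conc.loc["2020-05", "duration_h"] == 1.0
        assert conc.loc["2020-06", "duration_h"] == 2.0
        # frequency counted once, in the starting month
        assert conc.loc["2020-05", "frequency"] == 1
        assert conc.loc["2020-06", "frequency"] == 0

    def test_split_sums_to_total(self):
        rng = np.random.default_rng(6)
        rows = []
        t = pd.Timestamp("2020-05-15T00:00", tz="UTC")
        for _ in range(20):
            t = t + pd.Timedelta(hours=float(rng.integers(3, 200)))
            dur = pd.Timedelta(hours=float(rng.integers(1, 100)))
            rows.append(
                make_event(str(t.tz_localize(None)), str((t + dur).tz_localize(None)),
                           str(t.tz_localize(None)), str((t + dur).tz_localize(None)))
            )
        ev = events_frame(rows)
        seg = trace_segments(ev)
        out = monthly_summary(seg, ev[0:0])
        total_monthly = out[out["kind"] == "concurrent"]["duration_h"].sum()
        assert total_monthly == pytest.approx(seg["duration_h"].sum())


class TestPipelineOracle:
    def test_pipeline_equals_brute_force(self):
        rng = np.random.default_rng(7)
        pa = random_ppas(rng, 150, span_m=8000.0)
        pb = random_ppas(rng, 150, span_m=8000.0)
        events = find_events(pa, pb, max_lag_h=np.inf, lag_bins=())
        got = set(zip(events["i_a"], events["i_b"]))
        assert got == brute_force_intersections(pa, pb)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        pa = random_ppas(rng, 60, span_m=4000.0)
        pb = random_ppas(rng, 60, span_m=4000.0)
        res_ab = analyze_dyad(pa, pb, "a", "b")
        res_ba = analyze_dyad(pb, pa, "b", "a")
        assert len(res_ab.events) == len(res_ba.events)
        ab = set(zip(res_ab.events["i_a"], res_ab.events["i_b"]))
        ba = set(zip(res_ba.events["i_b"], res_ba.events["i_a"]))
        assert ab == ba
        assert res_ab.total_concurrent_duration_h == pytest.approx(
            res_ba.total_concurrent_duration_h
        )
        np.testing.assert_allclose(
            np.sort(res_ab.events["lag_h"]), np.sort(res_ba.events["lag_h"])
        )
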