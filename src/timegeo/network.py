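"""Aggregation of dyadic results into an interaction network.

Nodes are individuals with at least one interacting partner; edges
carry the concurrent-segment count, total duration, and duration per
month of shared tracking. Exports plain CSV plus GEXF for external
visualization tools.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .interaction import DyadResult


def _shared_months(track_a: pd.DataFrame, track_b: pd.DataFrame) -> int:
    """Calendar months with at least one fix from both individuals."""
    def months(track):
        t = track["t"]
        if t.dt.tz is not None:
            t = t.dt.tz_localize(None)
        return set(t.dt.to_period("M"))

    return len(months(track_a) & months(track_b))


def build_network(
    dyad_results: list[DyadResult],
    tracks: dict[str, pd.DataFrame] | None = None,
) -> tuple[nx.Graph, list[str]]:
    """Interaction graph over all analyzed dyads.

    An edge exists for every dyad with at least one concurrent segment;
    its weight attributes are the segment count, total duration (h) and
    duration per shared-tracking month. Individuals analyzed but never
    interacting are returned separately as isolates.

    Returns (graph, isolate ids).
    """
    g = nx.Graph()
    seen: set[str] = set()
    for res in dyad_results:
        seen.update(res.dyad)
        n_seg = len(res.concurrent_segments)
        if n_seg == 0:
            continue
        total_h = res.total_concurrent_duration_h
        months = 0
        if tracks is not None and res.id_a in tracks and res.id_b in tracks:
            months = _shared_months(tracks[res.id_a], tracks[res.id_b])
        per_month = total_h / months if months else float("nan")
        g.add_edge(
            res.id_a,
            res.id_b,
            n_concurrent_segments=n_seg,
            total_duration_h=total_h,
            duration_per_month_h=per_month,
            months_observed=months,
        )
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
        g.nodes[node]["total_duration_h"] = sum(
            d["total_duration_h"] for _, _, d in g.edges(node, data=True)
        )
    isolates = sorted(seen - set(g.nodes))
    return g, isolates


def network_frames(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(nodes, edges) tables for CSV export."""
    nodes = pd.DataFrame(
        [
            {"id": n, "degree": d.get("degree", 0),
             "total_duration_h": d.get("total_duration_h", 0.0)}
            for n, d in sorted(g.nodes(data=True))
        ],
        columns=["id", "degree", "total_duration_h"],
    )
    edges = pd.DataFrame(
        [
            {
                "source": min(u, v),
                "target": max(u, v),
                "n_concurrent_segments": d["n_concurrent_segments"],
                "total_duration_h": d["total_duration_h"],
                "duration_per_month_h": d["duration_per_month_h"],
                "months_observed": d["months_observed"],
            }
            for u, v, d in sorted(g.edges(data=True), key=lambda e: (min(e[:2]), max(e[:2])))
        ],
        columns=[
            "source", "target", "n_concurrent_segments",
            "total_duration_h", "duration_per_month_h", "months_observed",
        ],
    )
    return nodes, edges


def export_network(g: nx.Graph, out_dir, formats=("csv", "gexf")) -> list[str]:
    """Write nodes.csv/edges.csv and/or network.gexf under out_dir."""
    from pathlib import Path

    supported = {"csv", "gexf"}
    bad = set(formats) - supported
    if bad:
        raise ValueError(f"unsupported format(s) {sorted(bad)}; supported: {sorted(supported)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        nodes, edges = network_frames(g)
        nodes.to_csv(out_dir / "nodes.csv", index=False)
        edges.to_csv(out_dir / "edges.csv", index=False)
        written += ["nodes.csv", "edges.csv"]
    if "gexf" in formats:
        h = nx.Graph()
        h.add_nodes_from(g.nodes(data=True))
        for u, v, d in g.edges(data=True):
            h.add_edge(u, v, **{k: val for k, val in d.items() if val == val})
        nx.write_gexf(h, out_dir / "network.gexf")
        written.append("network.gexf")
    return written


def import_network_csv(nodes_path, edges_path) -> nx.Graph:
    """Rebuild a graph from the CSV pair written by export_network."""
    g = nx.Graph()
    nodes = pd.read_csv(nodes_path)
    for _, row in nodes.iterrows():
        g.add_node(
            str(row["id"]),
            degree=int(row["degree"]),
            total_duration_h=float(row["total_duration_h"]),
        )
    edges = pd.read_csv(edges_path)
    for _, row in edges.iterrows():
        g.add_edge(
            str(row["source"]),
            str(row["target"]),
            n_concurrent_segments=int(row["n_concurrent_segments"]),
            total_duration_h=float(row["total_duration_h"]),
            duration_per_month_h=float(row["duration_per_month_h"]),
            months_observed=int(row["months_observed"]),
        )
    return g
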