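"""Tabular I/O dialects: edge lists, node attributes, reports, SIF export.

All tables are tab-separated UTF-8 with '.' decimals; floating-point
fields are rounded to 10 decimals on write so output bundles are
byte-stable across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .association import PairwiseNetwork
from .netops import HubSet, TopologyReport
from .screen import ScreenResult

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_merged_edge_list",
    "read_merged_edge_list",
    "write_node_attributes",
    "write_sif",
    "write_screen_report",
    "write_topology_report",
]

FLOAT_FMT = "%.10g"


def write_edge_list(net: PairwiseNetwork, path: str | Path) -> None:
    """Cytoscape-importable edge list for one pairwise network."""
    pd.DataFrame(
        [
            {
                "source": fx,
                "target": fy,
                "weight": round(w, 10),
                "sign": s,
                "source_type": net.data_type_x,
                "target_type": net.data_type_y,
            }
            for fx, fy, w, s in net.edges
        ],
        columns=["source", "target", "weight", "sign", "source_type", "target_type"],
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_list(path: str | Path) -> PairwiseNetwork:
    df = pd.read_csv(path, sep="\t")
    required = {"source", "target", "weight", "sign", "source_type", "target_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty edge list")
    types_x = df["source_type"].unique()
    types_y = df["target_type"].unique()
    if len(types_x) != 1 or len(types_y) != 1:
        raise ValueError(f"{path}: a pairwise edge list must join two fixed types")
    net = PairwiseNetwork(
        data_type_x=str(types_x[0]),
        data_type_y=str(types_y[0]),
        edges=[
            (str(r.source), str(r.target), float(r.weight), int(r.sign))
            for r in df.itertuples()
        ],
        nodes_x=sorted(df["source"].astype(str).unique()),
        nodes_y=sorted(df["target"].astype(str).unique()),
    )
    net.n_components = nx.number_connected_components(net.to_graph())
    return net


def write_merged_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "weight": round(d["weight"], 10),
            "sign": d["sign"],
            "source_type": g.nodes[u]["data_type"],
            "target_type": g.nodes[v]["data_type"],
            "networks": ";".join(sorted(d["networks"])),
        }
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(
        rows,
        columns=[
            "source",
            "target",
            "weight",
            "sign",
            "source_type",
            "target_type",
            "networks",
        ],
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_merged_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for r in df.itertuples():
        nets = set(str(r.networks).split(";")) if "networks" in df.columns else set()
        for node, dtype in ((str(r.source), str(r.source_type)), (str(r.target), str(r.target_type))):
            if node in g and g.nodes[node]["data_type"] != dtype:
                raise ValueError(f"{path}: conflicting type for node {node!r}")
            if node not in g:
                g.add_node(node, data_type=dtype, networks=set())
            g.nodes[node]["networks"] |= nets
        g.add_edge(str(r.source), str(r.target), weight=float(r.weight), sign=int(r.sign), networks=nets)
    return g


def write_node_attributes(
    g: nx.Graph, hubs: HubSet | None, path: str | Path
) -> None:
    clustering = nx.clustering(g)
    rows = [
        {
            "node": n,
            "data_type": d["data_type"],
            "degree": g.degree(n),
            "clustering": round(clustering[n], 10),
            "hub": int(n in hubs.hubs) if hubs else 0,
        }
        for n, d in sorted(g.nodes(data=True))
    ]
    pd.DataFrame(
        rows, columns=["node", "data_type", "degree", "clustering", "hub"]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: ``source <sign> target`` per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, d in sorted(g.edges(data=True)):
            rel = "pos" if d.get("sign", 1) > 0 else "neg"
            fh.write(f"{u}\t{rel}\t{v}\n")


def write_screen_report(result: ScreenResult, path: str | Path) -> None:
    """Per-feature screen table: logFC/t/p/FDR per contrast + selected flag."""
    data: dict[str, object] = {"feature_id": result.feature_ids}
    for c, label in enumerate(result.contrast_labels):
        data[f"logFC[{label}]"] = result.log_fold_changes[:, c].round(10)
        data[f"t[{label}]"] = result.moderated_t[:, c].round(10)
        data[f"p[{label}]"] = result.p_values[:, c].round(10)
        data[f"fdr[{label}]"] = result.fdr[:, c].round(10)
    data["selected"] = [
        int(f in result.selected_features) for f in result.feature_ids
    ]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_topology_report(
    report: TopologyReport, hubs: HubSet | None, path: str | Path
) -> None:
    payload = report.to_dict()
    if hubs is not None:
        payload["n_hubs"] = len(hubs)
        payload["hubs"] = sorted(hubs.hubs)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
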