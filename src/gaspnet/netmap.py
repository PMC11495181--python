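"""Correlation feature maps: directed functional graphs and summaries.

Offset correlogram features become directed edges (peak -> excitation,
trough -> inhibition, source before target); central features become
undirected shared-influence edges (peak -> shared drive, trough -> shared
influences with opposite actions).  Unobserved common sources are not
synthesized as nodes: only the observable pairwise relation is drawn.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .core import SpikeTrain, ValidationError

EDGE_SIGNS = {("peak", "offset"): "excitation",
              ("trough", "offset"): "inhibition",
              ("peak", "central"): "shared_drive",
              ("trough", "central"): "shared_opposite"}


def build_feature_map(session, classes, edges: pd.DataFrame,
                      significant_only: bool = True) -> nx.MultiDiGraph:
    """Assemble the directed feature map from screened edges.

    ``classes`` maps neuron_id -> NeuronClassification (or label string);
    edge rows come from ``xcorr.screen_pairs``.  Undirected (central)
    relations are stored as a single edge with ``directed=False`` on the
    lexicographically ordered pair.
    """
    g = nx.MultiDiGraph()
    for tr in session.trains:
        cls = classes.get(tr.neuron_id) if classes else None
        label = getattr(cls, "label", cls) or "unclassified"
        g.add_node(tr.neuron_id, region=tr.region, cth_class=str(label),
                   n_spikes=tr.n_spikes)
    rows = edges[edges["significant"]] if significant_only and len(edges) \
        else edges
    for row in rows.itertuples():
        if row.source not in g or row.target not in g:
            raise ValidationError(
                f"edge references unknown neuron "
                f"{row.source}->{row.target}")
        sign = EDGE_SIGNS[(row.kind, row.position)]
        directed = row.position == "offset"
        a, b = ((row.source, row.target) if directed
                else sorted((row.source, row.target)))
        g.add_edge(a, b, sign=sign, directed=directed,
                   kind=row.kind, position=row.position,
                   extremum_lag_s=float(row.extremum_lag_s),
                   di=float(row.di), p_mc=float(row.p_mc),
                   q_value=float(row.q_value))
    return g


def summarize_connectivity(fmap: nx.MultiDiGraph,
                           per_group: str | None = "region") -> pd.DataFrame:
    """Per-group connectivity summary plus sign counts and the count of
    disinhibition motifs (A -| B -| C chains of directed inhibition)."""
    connected = {n for n in fmap
                 if fmap.degree(n) > 0}
    groups = {}
    for n, data in fmap.nodes(data=True):
        key = data.get(per_group, "all") if per_group else "all"
        groups.setdefault(key, []).append(n)

    inhib = [(u, v) for u, v, d in fmap.edges(data=True)
             if d["sign"] == "inhibition" and d["directed"]]
    motifs = sum(1 for (a, b) in inhib for (b2, c) in inhib
                 if b2 == b and c != a)

    rows = []
    for key in sorted(groups, key=str):
        members = groups[key]
        ncon = sum(1 for m in members if m in connected)
        rows.append({"group": key, "n_recorded": len(members),
                     "n_connected": ncon,
                     "fraction_connected": ncon / len(members)})
    total = {"group": "total", "n_recorded": fmap.number_of_nodes(),
             "n_connected": len(connected),
             "fraction_connected": (len(connected) / fmap.number_of_nodes()
                                    if fmap.number_of_nodes() else 0.0)}
    out = pd.DataFrame(rows + [total])
    sign_counts = pd.Series([d["sign"] for *_, d in fmap.edges(data=True)])
    for sign in ("excitation", "inhibition", "shared_drive",
                 "shared_opposite"):
        out[f"n_{sign}"] = int((sign_counts == sign).sum()) \
            if len(sign_counts) else 0
    out["n_disinhibition_motifs"] = motifs
    return out


def rate_heatmap_matrix(trains, bin_width: float,
                        interval=None):
    """Neurons x time-bins matrix of rates, each row scaled to its max.

    Silent rows stay all zero.  Returns ``(matrix, bin_edges, neuron_ids)``.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    trains = list(trains)
    if interval is None:
        interval = (min(t.interval[0] for t in trains),
                    max(t.interval[1] for t in trains))
    edges = np.arange(interval[0], interval[1] + bin_width, bin_width)
    mat = np.zeros((len(trains), edges.size - 1))
    for i, tr in enumerate(trains):
        counts = np.histogram(tr.times, bins=edges)[0]
        row = counts / bin_width
        if row.max() > 0:
            row = row / row.max()
        mat[i] = row
    return mat, edges, [t.neuron_id for t in trains]


def write_graphml(fmap: nx.MultiDiGraph, path) -> None:
    nx.write_graphml(fmap, path)


def read_graphml(path) -> nx.MultiDiGraph:
    return nx.read_graphml(path, force_multigraph=True)


def write_dot(fmap: nx.MultiDiGraph, path) -> None:
    """Minimal GraphViz export (no pydot dependency)."""
    lines = ["digraph feature_map {"]
    for n, d in fmap.nodes(data=True):
        lines.append(f'  "{n}" [region="{d.get("region", "")}" '
                     f'cth_class="{d.get("cth_class", "")}"];')
    style = {"excitation": "solid", "inhibition": "dashed",
             "shared_drive": "dotted", "shared_opposite": "dotted"}
    for u, v, d in fmap.edges(data=True):
        extra = "" if d.get("directed", True) else ", dir=none"
        lines.append(f'  "{u}" -> "{v}" [label="{d.get("sign", "")}", '
                     f'style={style.get(d.get("sign"), "solid")}{extra}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
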