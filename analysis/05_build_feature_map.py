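#!/usr/bin/env python
"""Assemble the correlation feature map and population summaries.

Combines the screened edges with the CTH classes into a directed graph
(offset peak -> excitation, offset trough -> inhibition, central features
-> undirected shared influence), exports GraphML/DOT, and prints the
per-region connectivity summary with the disinhibition-motif count and the
firing-rate heat-map matrix.
"""

import argparse
import os

import pandas as pd

from gaspnet import (build_feature_map, rate_heatmap_matrix,
                     read_session_dir, summarize_connectivity)
from gaspnet.netmap import write_dot, write_graphml

ap = argparse.ArgumentParser()
ap.add_argument("--session", default="results/session")
ap.add_argument("--out", default="results")
args = ap.parse_args()

session = read_session_dir(args.session)
edges = pd.read_csv(os.path.join(args.out, "edges.csv"))
classes = pd.read_csv(os.path.join(args.out, "classes.csv")) \
    .set_index("neuron_id")["label"].to_dict()

fmap = build_feature_map(session, classes, edges)
write_graphml(fmap, os.path.join(args.out, "feature_map.graphml"))
write_dot(fmap, os.path.join(args.out, "feature_map.dot"))

summary = summarize_connectivity(fmap)
summary.to_csv(os.path.join(args.out, "summary.csv"), index=False)
print(summary.to_string(index=False))

mat, bin_edges, ids = rate_heatmap_matrix(session.trains, bin_width=1.0)
pd.DataFrame(mat, index=ids).to_csv(os.path.join(args.out, "heatmap.csv"))
print(f"\nheat-map matrix: {mat.shape[0]} neurons x {mat.shape[1]} bins "
      f"(rows scaled to each neuron's maximum rate)")
edges_sig = edges[edges.significant]
for _, r in edges_sig.iterrows():
    arrow = "->" if r.position == "offset" else "--"
    print(f"  {r.source} {arrow} {r.target}: {r.kind} ({r.position}), "
          f"lag {r.extremum_lag_s*1e3:.1f} ms, DI {r.di:.1f}")
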