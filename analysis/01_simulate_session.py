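#!/usr/bin/env python
"""Simulate the bundled hypoxia-exposure session and write it to disk.

Generates the 20-neuron hypoxia_default scenario (control -> augmentation
-> apneusis with sighs -> apnea -> gasping -> recovery) with 12 injected
couplings and one latent common drive, then writes the session in the
delimited-text interchange format together with the ground truth needed by
the downstream recovery checks.
"""

import argparse
import json
import os

import numpy as np

from gaspnet import gen_session, hypoxia_default, validate_session, \
    write_session

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", default="results/session")
args = ap.parse_args()

scenario = hypoxia_default()
session, truth = gen_session(scenario, args.seed)
assert validate_session(session) == []

manifest = write_session(session, args.out)
truth_doc = {
    "seed": args.seed,
    "schedule": [(k, t0, t1) for k, t0, t1 in
                 truth.schedule.epoch_intervals()],
    "gasp_times": truth.gasp_times.tolist(),
    "sigh_times": truth.sigh_times.tolist(),
    "bp_step_times": truth.bp_step_times.tolist(),
    "connections": [{"source": c.source_id, "target": c.target_id,
                     "sign": c.sign, "latency": c.latency,
                     "width": c.kernel_width, "strength": c.strength}
                    for c in truth.connections],
    "neuron_classes": {s.neuron_id: s.pattern_class for s in truth.specs},
}
with open(os.path.join(args.out, "ground_truth.json"), "w") as fh:
    json.dump(truth_doc, fh, indent=1)

print(f"simulated {len(session.trains)} neurons over "
      f"{truth.schedule.total_duration:.0f} s "
      f"({sum(t.n_spikes for t in session.trains)} spikes), "
      f"{truth.cycles.n} respiratory cycles, "
      f"{truth.gasp_times.size} gasps")
print(f"wrote {len(manifest) + 1} files under {args.out}/")
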