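"""End-to-end orchestration: simulate/load -> segment -> classify -> screen
-> map -> report.

Stages mirror the analysis flow applied to each recording: respiratory
cycles are detected from the integrated phrenic signal; motor-pattern
epochs, sighs, gasps and blood-pressure steps are extracted; neurons are
classified from control-window CTHs; all pairs are screened for correlogram
features with FDR control; significant features become the correlation
feature map.  Everything is driven by one config and one seed, and a rerun
with the same (config, seed) reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import cth as cth_mod
from . import netmap, resp, synth, xcorr
from .core import AnalysisConfig, PreconditionError, Session, \
    validate_session, write_session

log = logging.getLogger("gaspnet")


@dataclasses.dataclass
class RunReport:
    config: dict
    seed: int
    n_trains: int = 0
    n_cycles: int = 0
    n_epochs: int = 0
    n_sighs: int = 0
    n_gasps: int = 0
    n_bp_steps: int = 0
    coincidence_count: int = 0
    n_classified: int = 0
    pairs_assessed: int = 0
    significant_pairs: int = 0
    n_edges: int = 0
    epoch_sequence: list = dataclasses.field(default_factory=list)
    warnings: list = dataclasses.field(default_factory=list)
    stage_seconds: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d.pop("stage_seconds")        # wall-clock; would break determinism
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    import yaml
    with open(config) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, out_dir=None, session: Session | None = None,
                 truth=None) -> RunReport:
    """Run every stage; returns the report (and writes all outputs if
    ``out_dir`` is given).

    ``config`` is a dict or YAML path with optional keys ``scenario``
    (name or scenario dict; default hypoxia_default), ``seed``,
    ``analysis`` (AnalysisConfig overrides), ``run_sta`` and
    ``screen_epochs`` (restrict correlogram screening to labeled epoch
    classes).  A precomputed ``session`` bypasses simulation.
    """
    t_all = time.time()
    cfg_in = _load_config(config)
    seed = int(cfg_in.get("seed", 0))
    acfg = AnalysisConfig(**cfg_in.get("analysis", {})).replace(
        rng_seed=seed)
    acfg.validate()
    report = RunReport(config=cfg_in, seed=seed)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    marker = os.path.join(out_dir, ".partial") if out_dir else None
    if marker:
        open(marker, "w").close()

    def stage(name):
        log.info("stage %s", name)
        report.stage_seconds[name] = time.time()

    def done(name):
        report.stage_seconds[name] = time.time() \
            - report.stage_seconds[name]
        log.info("stage %s done in %.2fs", name, report.stage_seconds[name])

    try:
        stage("simulate")
        if session is None:
            scen = cfg_in.get("scenario", "hypoxia_default")
            if isinstance(scen, str):
                if scen != "hypoxia_default":
                    raise PreconditionError(f"unknown scenario {scen!r}")
                scenario = synth.hypoxia_default()
            else:
                scenario = synth.ScenarioConfig.from_dict(scen)
            session, truth = synth.gen_session(scenario, seed)
        bad = validate_session(session)
        if bad:
            raise PreconditionError("invalid session: " + "; ".join(bad))
        report.n_trains = len(session.trains)
        if out_dir:
            write_session(session, os.path.join(out_dir, "session"))
        done("simulate")

        stage("cycles")
        phrenic = session.signals.get("phrenic_integrated")
        if phrenic is None:
            raise PreconditionError("session lacks phrenic_integrated")
        cycles = resp.detect_cycles(phrenic, acfg,
                                    control_window=session.control_window)
        report.n_cycles = cycles.n
        done("cycles")

        stage("epochs")
        if session.control_window is None:
            raise PreconditionError(
                "session has no control window (CTH classification needs a "
                "normoxic control period)")
        epochs, sighs = resp.classify_epochs(phrenic, cycles,
                                             session.control_window, acfg)
        gasps = resp.detect_gasps(phrenic, epochs, acfg, cycles=cycles,
                                  control_window=session.control_window)
        report.n_epochs = len(epochs)
        report.n_sighs = len(sighs)
        report.n_gasps = len(gasps)
        report.epoch_sequence = [e.kind for e in epochs]
        if out_dir:
            resp.epochs_to_frame(epochs).to_csv(
                os.path.join(out_dir, "epochs.csv"), index=False)
        done("epochs")

        stage("classify")
        ctrl_cycles = cycles.in_window(session.control_window)
        if ctrl_cycles.n < 2:
            raise PreconditionError("control window has <2 cycles; cannot "
                                    "classify CTHs")
        classes = {}
        cths = {}
        for tr in session.trains:
            c, cls = cth_mod.classify_train(tr, ctrl_cycles, acfg,
                                            seed=seed)
            classes[tr.neuron_id] = cls
            cths[tr.neuron_id] = c
        report.n_classified = len(classes)
        if out_dir:
            pd.DataFrame(
                [{"neuron_id": k, "modulation": v.modulation,
                  "subtype": v.subtype, "tonicity": v.tonicity,
                  "p_testA": v.p_testA, "p_testB": v.p_testB,
                  "mean_rate": v.mean_rate}
                 for k, v in sorted(classes.items())]).to_csv(
                os.path.join(out_dir, "classes.csv"), index=False)
            rows = []
            for nid, c in sorted(cths.items()):
                for ctr, r, sr in zip(c.bin_centers, c.rate_per_bin,
                                      c.scaled_rate):
                    rows.append({"neuron_id": nid, "bin_center_phase": ctr,
                                 "rate": r, "scaled_rate": sr})
            pd.DataFrame(rows).to_csv(os.path.join(out_dir, "cth.csv"),
                                      index=False)
        done("classify")

        stage("gasp_sync")
        bp = session.signals.get("blood_pressure")
        if bp is not None:
            label_map = {k: v.label for k, v in classes.items()}
            steps, sync, coinc = resp.detect_bp_steps_and_sync(
                bp, gasps, session.trains, acfg, classes=label_map)
            report.n_bp_steps = len(steps)
            report.coincidence_count = coinc
            if out_dir:
                resp.events_to_frame(sighs + gasps + steps).to_csv(
                    os.path.join(out_dir, "events.csv"), index=False)
                sync.to_csv(os.path.join(out_dir, "sync_table.csv"),
                            index=False)
        done("gasp_sync")

        stage("screen")
        screen_epochs = cfg_in.get("screen_epochs")
        trains = session.trains
        if screen_epochs:
            keep = [(e.t0, e.t1) for e in epochs if e.kind in screen_epochs]
            trains = [_restrict(tr, keep) for tr in session.trains]
        edges, screen_rep = xcorr.screen_pairs(trains, acfg, seed=seed)
        report.pairs_assessed = screen_rep["n_pairs_assessed"]
        report.significant_pairs = screen_rep["n_significant_pairs"]
        report.warnings.extend(
            f"pair skipped: {a}-{b}: {why}"
            for a, b, why in screen_rep["skipped"])
        if out_dir:
            edges.to_csv(os.path.join(out_dir, "edges.csv"), index=False)
        done("screen")

        if cfg_in.get("run_sta"):
            stage("sta")
            from . import sta as sta_mod
            rows = []
            for tr in session.trains:
                try:
                    s = sta_mod.spike_triggered_average(phrenic, tr,
                                                        acfg.sta_window)
                    sta_mod.detect_sta_features(s, acfg, seed=seed)
                except PreconditionError as err:
                    report.warnings.append(f"sta {tr.neuron_id}: {err}")
                    continue
                for f in s.features:
                    rows.append({"trigger": tr.neuron_id, "kind": f.kind,
                                 "position": f.position, "lag_s": f.lag,
                                 "p_mc": f.p_mc,
                                 "significant": f.significant,
                                 "premotor": f.premotor,
                                 "inhibitory": f.inhibitory})
            if out_dir:
                pd.DataFrame(rows).to_csv(
                    os.path.join(out_dir, "sta_features.csv"), index=False)
            done("sta")

        stage("map")
        fmap = netmap.build_feature_map(session, classes, edges)
        summary = netmap.summarize_connectivity(fmap)
        report.n_edges = fmap.number_of_edges()
        if out_dir:
            netmap.write_graphml(fmap, os.path.join(out_dir,
                                                    "feature_map.graphml"))
            netmap.write_dot(fmap, os.path.join(out_dir, "feature_map.dot"))
            summary.to_csv(os.path.join(out_dir, "summary.csv"),
                           index=False)
            mat, edges_t, ids = netmap.rate_heatmap_matrix(session.trains,
                                                           bin_width=1.0)
            pd.DataFrame(mat, index=ids).to_csv(
                os.path.join(out_dir, "heatmap.csv"))
        done("map")
    except Exception:
        log.exception("pipeline aborted; partial outputs retained")
        raise
    if marker:
        os.remove(marker)
    if out_dir:
        report.to_json(os.path.join(out_dir, "report.json"))
    log.info("pipeline finished in %.1fs", time.time() - t_all)
    return report


def _restrict(tr, windows):
    from .core import SpikeTrain
    keep = np.zeros(tr.times.size, dtype=bool)
    for a, b in windows:
        keep |= (tr.times >= a) & (tr.times < b)
    return SpikeTrain(tr.neuron_id, tr.times[keep], tr.interval, tr.region)
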