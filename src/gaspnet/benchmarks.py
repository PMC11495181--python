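"""Operating-characteristic benchmarks for the screening pipeline.

These routines measure, on synthetic data with known ground truth, the
procedure-level properties the analysis is designed to guarantee: the
realized frequency of false-positive pair detections under the FDR-
controlled screen, the detectability index reached by a strongly coupled
pair, recovery of injected connections, and recovery of generated CTH
classes.  They are used by the acceptance script and the acceptance tests.
"""

from __future__ import annotations

import numpy as np

from . import synth, xcorr
from .core import AnalysisConfig, SpikeTrain
from .cth import classify_train


def _poisson_train(rng, rate, duration, nid):
    n = rng.poisson(rate * duration)
    return SpikeTrain(nid, np.sort(rng.uniform(0.0, duration, n)),
                      (0.0, duration))


def fdr_replicate(seed: int, n_pairs: int = 100, rate: float = 10.0,
                  duration: float = 300.0,
                  n_surrogates: int = 200) -> int:
    """One replicate of the null screen: ``n_pairs`` mutually independent
    Poisson pairs through the full screening procedure; returns the number
    of pairs declared significant (0 expected under the FDR bound)."""
    rng = np.random.default_rng(seed)
    trains = []
    pairs = []
    for k in range(n_pairs):
        a = _poisson_train(rng, rate, duration, f"a{k:03d}")
        b = _poisson_train(rng, rate, duration, f"b{k:03d}")
        trains += [a, b]
        pairs.append((a.neuron_id, b.neuron_id))
    cfg = AnalysisConfig(n_surrogates=n_surrogates)
    edges, report = xcorr.screen_pairs(trains, cfg, pairs=pairs, seed=seed)
    return int(report["n_significant_pairs"])


def fdr_calibration(seed: int, n_replicates: int = 50, n_pairs: int = 100,
                    n_surrogates: int = 200, verbose: bool = False):
    """Fraction of replicates in which any independent pair is declared
    significant, with the count of replicates."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    hits = 0
    for i, s in enumerate(seeds):
        k = fdr_replicate(int(s % (2 ** 31)), n_pairs=n_pairs,
                          n_surrogates=n_surrogates)
        hits += k > 0
        if verbose:
            print(f"  replicate {i + 1}/{n_replicates}: "
                  f"{k} significant pairs", flush=True)
    return hits / n_replicates, n_replicates


def coupled_pair_di(seed: int, strength: float = 3.0,
                    latency: float = 0.001, width: float = 0.002,
                    rate: float = 10.0, duration: float = 600.0,
                    n_surrogates: int = 1000):
    """Detectability index of the offset peak for a strongly coupled
    excitatory pair; returns (di, n_ref_spikes)."""
    specs = [synth.NeuronSpec("ref", "other", "NRM", rate, 0.0),
             synth.NeuronSpec("tgt", "other", "NRM", rate, 0.0)]
    conn = [synth.ConnectionSpec("ref", "tgt", "excitatory", latency,
                                 width, strength)]
    sched = synth.PatternSchedule(
        epochs=[synth.EpochSpec("control", duration)])
    trains, _ = synth.sample_coupled_population(specs, conn, [], sched,
                                                seed)
    cfg = AnalysisConfig(n_surrogates=n_surrogates)
    edges, _ = xcorr.screen_pairs(trains, cfg, seed=seed)
    off = edges[(edges.kind == "peak") & (edges.position == "offset")
                & (edges.extremum_lag_s > 0)
                & (edges.extremum_lag_s <= latency + width + 0.001)]
    di = float(off.di.max()) if len(off) else 0.0
    return di, trains[0].n_spikes


def connection_recovery(seed: int, config: AnalysisConfig | None = None):
    """Screen one hypoxia_default session; returns a dict with recovered /
    missed connections and false edges on independent pairs."""
    cfg = config or AnalysisConfig()
    session, truth = synth.gen_session(synth.hypoxia_default(), seed)
    edges, report = xcorr.screen_pairs(session, cfg, seed=seed)
    sig = edges[edges.significant]
    recovered = []
    for c in truth.connections:
        want = "peak" if c.sign == "excitatory" else "trough"
        m = sig[(sig.source == c.source_id) & (sig.target == c.target_id)
                & (sig.position == "offset") & (sig.kind == want)
                & (sig.extremum_lag_s >= c.latency)
                & (sig.extremum_lag_s <= c.latency + c.kernel_width)]
        recovered.append(len(m) > 0)
    indep = set(map(frozenset, truth.independent_pairs()))
    false_edges = int(sum(frozenset((s, t)) in indep
                          for s, t in zip(sig.source, sig.target)))
    return {"n_connections": len(truth.connections),
            "n_recovered": int(sum(recovered)),
            "false_edges": false_edges,
            "n_independent_pairs": len(indep),
            "n_significant_pairs": report["n_significant_pairs"]}


def cth_recovery_population(n_per_class: int = 25):
    """200-neuron population covering I/E x Aug/Dec x phasic/tonic.

    Phasic cells use the half-wave profile (full modulation by
    construction); tonic cells use the cosine profile at depth 0.8 with the
    peak placed to realize each Aug/Dec label.
    """
    layout = [
        (dict(pattern_class="I-Aug", depth=0.8), "I-Aug", "phasic"),
        (dict(pattern_class="I-Dec", depth=0.8), "I-Dec", "phasic"),
        (dict(pattern_class="E-Aug", depth=0.8), "E-Aug", "phasic"),
        (dict(pattern_class="E-Dec", depth=0.8), "E-Dec", "phasic"),
        (dict(pattern_class="tonic-I", depth=0.8, peak_phase=0.375),
         "I-Aug", "tonic"),
        (dict(pattern_class="tonic-I", depth=0.8, peak_phase=0.125),
         "I-Dec", "tonic"),
        (dict(pattern_class="tonic-E", depth=0.8, peak_phase=0.875),
         "E-Aug", "tonic"),
        (dict(pattern_class="tonic-E", depth=0.8, peak_phase=0.625),
         "E-Dec", "tonic"),
    ]
    specs, wanted = [], []
    for j, (kw, label, ton) in enumerate(layout):
        for i in range(n_per_class):
            specs.append(synth.NeuronSpec(f"c{j}_{i:02d}", "VRC",
                                          base_rate=10.0, **kw))
            wanted.append((label, ton))
    return specs, wanted


def cth_recovery(seed: int, n_per_class: int = 25, n_cycles: int = 100,
                 n_shuffles: int = 300):
    """Fraction of generated neurons whose full class label
    (I/E x Aug/Dec x phasic/tonic) is recovered from control-window CTHs."""
    sched = synth.PatternSchedule(
        epochs=[synth.EpochSpec("control", n_cycles * 2.55 + 5)])
    cycles, _ = synth.gen_cycles(sched, seed)
    specs, wanted = cth_recovery_population(n_per_class)
    trains, _ = synth.sample_coupled_population(
        specs, [], [], sched, seed, cycles=cycles,
        gasp_times=np.empty(0))
    cfg = AnalysisConfig(cth_n_shuffles=n_shuffles)
    hits = 0
    for tr, (label, ton) in zip(trains, wanted):
        _, cls = classify_train(tr, cycles, cfg, seed=seed)
        hits += (cls.label == label and cls.tonicity == ton)
    return hits / len(trains), len(trains)


def modulation_type1(seed: int, n_sims: int = 400, n_cycles: int = 100,
                     rate: float = 10.0, n_shuffles: int = 200,
                     alpha: float = 0.05):
    """Type-I error of the two modulation tests under homogeneous Poisson
    firing on symmetric (equal I/E) cycles; returns (rateA, rateB, n)."""
    from .cth import test_modulation
    from .resp import CycleSet
    rng = np.random.default_rng(seed)
    i_on = np.arange(n_cycles) * 2.5
    cycles = CycleSet(i_on, i_on + 1.25, i_on + 2.5)
    duration = n_cycles * 2.5
    rej_a = rej_b = 0
    for s in range(n_sims):
        n = rng.poisson(rate * duration)
        tr = SpikeTrain("n", np.sort(rng.uniform(0, duration, n)),
                        (0.0, duration))
        p_a, p_b, _ = test_modulation(tr, cycles, alpha=alpha,
                                      n_shuffles=n_shuffles,
                                      seed=int(rng.integers(2 ** 31)))
        rej_a += p_a < alpha
        rej_b += p_b < alpha
    return rej_a / n_sims, rej_b / n_sims, n_sims
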