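"""Motor-pattern segmentation of the integrated phrenic signal.

Cycle detection uses hysteresis thresholding of a smoothed copy of the
signal: inspiration starts at an upward crossing of ``theta_on`` and ends at
a downward crossing of ``theta_off < theta_on``; both thresholds are derived
from the control window (baseline + k * (peak - baseline)).

Epoch labeling compares per-cycle features (peak amplitude, inspiratory
duration, cycle duration) with control statistics:

* augmentation — amplitude or frequency above control mean + z*SD for at
  least ``n_consec`` consecutive cycles;
* apneusis — inspiratory duration above ``a`` times the control median;
* sigh (augmented breath) — within-cycle peak above ``s`` times the control
  median peak, late in inspiration;
* apnea — no detected cycle for longer than ``T_apnea``;
* gasp — a burst during or after an apnea epoch with a decrementing shape
  (time-to-peak under ``f`` of the burst duration) and a duration shorter
  than the control median inspiratory duration;
* gasping — the span of two or more consecutive gasps (the quasiperiodic
  silences between gasps belong to the gasping epoch, not to apnea);
* recovery — control-like cycles after the perturbation.

The classification rules are explicit, config-exposed operational versions
of pattern labels that are assigned by expert inspection on real records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import AnalysisConfig, ContinuousSignal, PreconditionError


@dataclass
class CycleSet:
    """Detected respiratory cycles (same shape as the generator's truth)."""

    i_onset: np.ndarray
    e_onset: np.ndarray
    end: np.ndarray
    peak_amp: np.ndarray = None
    peak_time: np.ndarray = None
    flat_signal: bool = False

    @property
    def n(self) -> int:
        return int(self.i_onset.size)

    def in_window(self, window) -> "CycleSet":
        m = (self.i_onset >= window[0]) & (self.end <= window[1])
        return CycleSet(self.i_onset[m], self.e_onset[m], self.end[m],
                        self.peak_amp[m] if self.peak_amp is not None
                        else None,
                        self.peak_time[m] if self.peak_time is not None
                        else None)


@dataclass
class EpochLabel:
    t0: float
    t1: float
    kind: str


@dataclass
class MotorEvent:
    kind: str          # sigh | gasp | bp_step
    time: float
    magnitude: float


def _smooth(sig: ContinuousSignal, width: float) -> np.ndarray:
    w = max(int(round(width * sig.fs)), 1)
    kernel = np.ones(w) / w
    return np.convolve(sig.samples, kernel, mode="same")


def detect_cycles(phrenic: ContinuousSignal,
                  config: AnalysisConfig | None = None,
                  control_window=None) -> CycleSet:
    """Hysteresis segmentation of phrenic bursts into respiratory cycles.

    A flat signal returns an empty cycle set with ``flat_signal=True``
    rather than raising.
    """
    cfg = config or AnalysisConfig()
    s = _smooth(phrenic, cfg.smooth_width)
    t = phrenic.times()
    if control_window is not None:
        m = (t >= control_window[0]) & (t < control_window[1])
        ref = s[m] if m.any() else s
    else:
        ref = s
    baseline = np.percentile(ref, 5)
    peak = np.percentile(ref, 95)
    if peak - baseline < 1e-9 * max(abs(peak), 1.0) or peak <= baseline:
        return CycleSet(*(np.empty(0),) * 3, np.empty(0), np.empty(0),
                        flat_signal=True)
    th_on = baseline + cfg.cycle_k_on * (peak - baseline)
    th_off = baseline + cfg.cycle_k_off * (peak - baseline)

    above_on = s >= th_on
    below_off = s < th_off
    ups = np.flatnonzero(above_on[1:] & ~above_on[:-1]) + 1
    downs = np.flatnonzero(below_off[1:] & ~below_off[:-1]) + 1

    i_on, e_on, amp, ptime = [], [], [], []
    di = 0
    for u in ups:
        # ignore re-arms before the previous burst switched off
        if e_on and t[u] <= e_on[-1]:
            continue
        while di < downs.size and downs[di] <= u:
            di += 1
        if di >= downs.size:
            # final burst never switches off; drop it
            break
        d = downs[di]
        seg = slice(u, d)
        i_on.append(t[u])
        e_on.append(t[d])
        amp.append(float(s[seg].max()))
        ptime.append(float(t[u + int(np.argmax(s[seg]))]))
    i_on = np.array(i_on)
    e_on = np.array(e_on)
    if i_on.size == 0:
        return CycleSet(*(np.empty(0),) * 3, np.empty(0), np.empty(0),
                        flat_signal=False)
    e_dur = e_on[:-1] - i_on[:-1]
    med_e = (np.median(i_on[1:] - e_on[:-1]) if i_on.size > 1
             else max(float(np.median(e_on - i_on)), 0.1))
    end = np.concatenate([i_on[1:],
                          [min(e_on[-1] + max(med_e, 0.05), t[-1] + 1 /
                               phrenic.fs)]])
    return CycleSet(i_on, e_on, end, np.array(amp), np.array(ptime))


@dataclass
class _Segmentation:
    cycles: CycleSet
    cycle_kind: np.ndarray          # per-cycle label
    epochs: list
    sighs: list
    gasps: list
    control_stats: dict


def _segment(phrenic, cycles: CycleSet, control_window, cfg) -> _Segmentation:
    ctrl = cycles.in_window(control_window)
    if ctrl.n < 10:
        raise PreconditionError(
            f"control window holds {ctrl.n} cycles; >= 10 required")
    i_dur = ctrl.e_onset - ctrl.i_onset
    cyc_dur = ctrl.end - ctrl.i_onset
    stats = {
        "amp_mean": float(np.mean(ctrl.peak_amp)),
        "amp_sd": float(np.std(ctrl.peak_amp, ddof=1)),
        "amp_median": float(np.median(ctrl.peak_amp)),
        "i_median": float(np.median(i_dur)),
        "cyc_median": float(np.median(cyc_dur)),
        "freq_mean": float(np.mean(1.0 / cyc_dur)),
        "freq_sd": float(np.std(1.0 / cyc_dur, ddof=1)),
    }
    t_apnea = max(cfg.apnea_cycle_factor * stats["cyc_median"],
                  cfg.apnea_floor)

    n = cycles.n
    i_dur_all = cycles.e_onset - cycles.i_onset
    freq_all = 1.0 / (cycles.end - cycles.i_onset)
    tpk = cycles.peak_time - cycles.i_onset

    apneustic = i_dur_all > cfg.apneusis_factor * stats["i_median"]
    elevated = ((cycles.peak_amp > stats["amp_mean"]
                 + cfg.augment_z * stats["amp_sd"])
                | (freq_all > stats["freq_mean"]
                   + cfg.augment_z * stats["freq_sd"]))
    augmented = np.zeros(n, dtype=bool)
    run = 0
    for k in range(n + 1):
        if k < n and elevated[k] and not apneustic[k]:
            run += 1
        else:
            if run >= cfg.augment_n_consec:
                augmented[k - run:k] = True
            run = 0
    sigh = ((cycles.peak_amp > cfg.sigh_factor * stats["amp_median"])
            & (tpk > 0.5 * i_dur_all))

    # apnea gaps between consecutive bursts
    gaps = []
    for k in range(n - 1):
        if cycles.i_onset[k + 1] - cycles.e_onset[k] > t_apnea:
            gaps.append((float(cycles.e_onset[k]),
                         float(cycles.i_onset[k + 1])))
    first_apnea = gaps[0][0] if gaps else np.inf

    gasp = ((cycles.i_onset >= first_apnea)
            & (tpk < cfg.gasp_tpk_frac * i_dur_all)
            & (i_dur_all < stats["i_median"]))

    kind = np.full(n, "", dtype=object)
    seen_abnormal = False
    for k in range(n):
        if gasp[k]:
            kind[k] = "gasp"
            seen_abnormal = True
        elif apneustic[k]:
            kind[k] = "apneusis"
            seen_abnormal = True
        elif augmented[k]:
            kind[k] = "augmentation"
            seen_abnormal = True
        elif cycles.i_onset[k] < control_window[1] or not seen_abnormal:
            kind[k] = "control"
        else:
            kind[k] = "recovery"

    # runs of same-kind cycles become epoch segments; consecutive gasps
    # merge into one gasping epoch that absorbs the inter-gasp silences
    gasp_idx = np.flatnonzero(kind == "gasp")
    t_start = (float(phrenic.start) if cycles.n == 0
               else min(float(phrenic.start), float(cycles.i_onset[0])))
    t_end = float(phrenic.end)
    segs = []          # (label, start, end, off-time of final burst)
    k = 0
    while k < n:
        lab = kind[k]
        j = k
        while j + 1 < n and kind[j + 1] == lab:
            j += 1
        segs.append(("gasping" if lab == "gasp" else lab,
                     float(cycles.i_onset[k]), float(cycles.end[j]),
                     float(cycles.e_onset[j])))
        k = j + 1
    # apnea segments fill burst-free stretches longer than the threshold
    # (measured from the last burst's off-transition to the next onset)
    e_median = stats["cyc_median"] - stats["i_median"]
    with_apnea = []
    for idx, (lab, a, b, off) in enumerate(segs):
        with_apnea.append((lab, a, b))
        if idx + 1 < len(segs) and segs[idx + 1][1] - off > t_apnea:
            # silence starts where the last expiration would have ended
            with_apnea.append(("apnea", off + e_median, segs[idx + 1][1]))
    segs = with_apnea

    # tile [t_start, t_end]: each epoch runs to the next segment's start
    epochs = []
    for idx, (lab, a, b) in enumerate(segs):
        a0 = t_start if idx == 0 else epochs[-1].t1
        b0 = segs[idx + 1][1] if idx + 1 < len(segs) else t_end
        epochs.append(EpochLabel(a0, b0, lab))
    if not epochs:
        epochs = [EpochLabel(t_start, t_end, "control")]

    sigh_events = [MotorEvent("sigh", float(cycles.peak_time[k]),
                              float(cycles.peak_amp[k]))
                   for k in np.flatnonzero(sigh & (kind != "gasp")
                                           & (kind != "control"))]
    gasp_events = [MotorEvent("gasp", float(cycles.i_onset[k]),
                              float(cycles.peak_amp[k]))
                   for k in gasp_idx]
    return _Segmentation(cycles, kind, epochs, sigh_events, gasp_events,
                         stats)


def classify_epochs(phrenic: ContinuousSignal, cycles: CycleSet,
                    control_window, config: AnalysisConfig | None = None):
    """Label motor-pattern epochs; returns ``(epochs, sigh_events)``."""
    cfg = config or AnalysisConfig()
    seg = _segment(phrenic, cycles, control_window, cfg)
    return seg.epochs, seg.sighs


def detect_gasps(phrenic: ContinuousSignal, epochs,
                 config: AnalysisConfig | None = None,
                 cycles: CycleSet | None = None,
                 control_window=None) -> list:
    """Gasp events (burst onsets) during/after apnea epochs."""
    cfg = config or AnalysisConfig()
    if control_window is None:
        ctrl = [e for e in epochs if e.kind == "control"]
        if not ctrl:
            return []
        control_window = (ctrl[0].t0, ctrl[0].t1)
    if cycles is None:
        cycles = detect_cycles(phrenic, cfg, control_window=control_window)
    seg = _segment(phrenic, cycles, control_window, cfg)
    return seg.gasps


def detect_bp_steps_and_sync(bp: ContinuousSignal, gasps, trains,
                             config: AnalysisConfig | None = None,
                             classes: dict | None = None):
    """BP steps, gasp/step coincidence, and the gasp-synchrony table.

    A step is a sustained rise exceeding ``bp_step_height`` achieved within
    ``bp_step_window`` seconds on a median-filtered trace.  A neuron is
    gasp-synchronous if its rate within +/- ``gasp_sync_window`` of at least
    ``gasp_sync_min_frac`` of gasp onsets exceeds ``gasp_sync_rate_factor``
    times its session-median rate.  ``classes`` (neuron_id -> control
    pattern label) annotates synchronous control-silent cells as
    non-respiratory-modulated, mirroring the observation that cells bursting
    during gasps need not be inspiratory during control.
    """
    cfg = config or AnalysisConfig()
    w = max(int(round(cfg.bp_median_width * bp.fs)) | 1, 3)
    m = ndimage.median_filter(bp.samples, size=w, mode="nearest")
    lag = int(round(cfg.bp_step_window * bp.fs))
    rise = m[lag:] - m[:-lag]
    high = rise > cfg.bp_step_height
    starts = np.flatnonzero(high[1:] & ~high[:-1]) + 1
    if high.size and high[0]:
        starts = np.concatenate([[0], starts])
    t = bp.times()
    steps = [MotorEvent("bp_step", float(t[s + lag // 2]),
                        float(rise[s:min(s + lag, rise.size)].max()))
             for s in starts]

    gasp_times = np.array([g.time for g in gasps])
    step_times = np.array([s.time for s in steps])
    coincidence = int(np.sum([
        np.any(np.abs(step_times - gt) <= 2.0) for gt in gasp_times])) \
        if step_times.size else 0

    rows = []
    if gasp_times.size:
        for tr in trains:
            t0, t1 = tr.interval
            nbins = max(int(t1 - t0), 1)
            binned = np.histogram(tr.times, bins=nbins,
                                  range=(t0, t0 + nbins))[0]
            med_rate = float(np.median(binned))
            thr = cfg.gasp_sync_rate_factor * med_rate
            width = 2 * cfg.gasp_sync_window
            hits = 0
            for gt in gasp_times:
                c = np.searchsorted(tr.times, gt + cfg.gasp_sync_window) \
                    - np.searchsorted(tr.times, gt - cfg.gasp_sync_window)
                if c / width > thr:
                    hits += 1
            if hits / gasp_times.size >= cfg.gasp_sync_min_frac and hits > 0:
                label = (classes or {}).get(tr.neuron_id, "unknown")
                rows.append({"neuron_id": tr.neuron_id,
                             "n_gasps_active": hits,
                             "frac_gasps_active": hits / gasp_times.size,
                             "control_class": label})
    sync = pd.DataFrame(rows, columns=["neuron_id", "n_gasps_active",
                                       "frac_gasps_active", "control_class"])
    return steps, sync, coincidence


def epochs_to_frame(epochs) -> pd.DataFrame:
    return pd.DataFrame([{"t0": e.t0, "t1": e.t1, "class": e.kind}
                         for e in epochs])


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame([{"kind": e.kind, "time": e.time,
                          "magnitude": e.magnitude} for e in events],
                        columns=["kind", "time", "magnitude"])
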