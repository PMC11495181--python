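"""Spike-triggered averages of (full-wave-rectified) continuous signals.

The STA averages the signal in a lag window around every trigger spike.
Rectification takes the absolute deviation from the signal median (nerve
recordings carry DC offsets, so the median — not zero — is the baseline).
Significance bands come from surrogate trigger trains with gamma-distributed
ISIs, exactly as in the correlogram screening: an offset peak at positive
lag is consistent with a premotor function, an offset trough with
functional inhibition of the downstream drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnalysisConfig, ContinuousSignal, PreconditionError, \
    SpikeTrain
from .xcorr import fit_gamma_shape, _surrogate_isis


@dataclass
class StaFeature:
    kind: str            # peak | trough
    position: str        # central | offset
    lag: float           # s, extremum
    extent: tuple        # (lag_lo, lag_hi)
    departure: float     # signal units above/below surrogate mean
    p_mc: float
    significant: bool
    premotor: bool = False
    inhibitory: bool = False


@dataclass
class SpikeTriggeredAverage:
    trigger_id: str
    signal_name: str
    lags: np.ndarray
    mean_trace: np.ndarray
    n_triggers: int
    n_excluded: int
    rectify: bool
    baseline: float
    surrogate_mean: np.ndarray | None = None
    surrogate_lo: np.ndarray | None = None
    surrogate_hi: np.ndarray | None = None
    features: list = field(default_factory=list)
    _trigger: SpikeTrain | None = None
    _signal: ContinuousSignal | None = None


def _sta_trace(values, fs, start, spike_times, n_lag):
    idx = np.rint((spike_times - start) * fs).astype(np.int64)
    ok = (idx - n_lag >= 0) & (idx + n_lag < values.size)
    used = idx[ok]
    if used.size == 0:
        return None, 0, int(idx.size)
    offs = np.arange(-n_lag, n_lag + 1)
    trace = values[used[:, None] + offs[None, :]].mean(axis=0)
    return trace, int(used.size), int(idx.size - used.size)


def spike_triggered_average(signal: ContinuousSignal, trigger: SpikeTrain,
                            window: float = 0.1,
                            rectify: bool = True) -> SpikeTriggeredAverage:
    """Average of the signal around each trigger spike.

    Triggers whose window extends past the signal are excluded and counted
    in ``n_excluded``; with none usable an error is raised.
    """
    n_lag = int(round(window * signal.fs))
    baseline = float(np.median(signal.samples)) if rectify else 0.0
    values = np.abs(signal.samples - baseline) if rectify \
        else signal.samples.astype(float)
    trace, n_used, n_exc = _sta_trace(values, signal.fs, signal.start,
                                      trigger.times, n_lag)
    if trace is None:
        raise PreconditionError(
            f"no trigger of {trigger.neuron_id} has full window coverage")
    lags = np.arange(-n_lag, n_lag + 1) / signal.fs
    return SpikeTriggeredAverage(
        trigger_id=trigger.neuron_id, signal_name=signal.name, lags=lags,
        mean_trace=trace, n_triggers=n_used, n_excluded=n_exc,
        rectify=rectify, baseline=baseline, _trigger=trigger,
        _signal=signal)


def detect_sta_features(sta: SpikeTriggeredAverage,
                        config: AnalysisConfig | None = None,
                        seed: int = 0) -> list:
    """Surrogate-band feature detection on an STA.

    Surrogate STAs are triggered on gamma-ISI surrogate trains; features are
    runs of at least ``min_feature_bins`` samples outside the pointwise 95%
    band, with a max-statistic Monte Carlo p-value as in the correlogram
    screening.  Offset peaks (troughs) at positive lag set the premotor
    (inhibitory) flag.
    """
    cfg = config or AnalysisConfig()
    trigger, signal = sta._trigger, sta._signal
    if trigger is None or signal is None:
        raise PreconditionError("STA lacks trigger/signal references")
    values = np.abs(signal.samples - sta.baseline) if sta.rectify \
        else signal.samples.astype(float)
    n_lag = (sta.lags.size - 1) // 2

    shape, mean_isi = fit_gamma_shape(trigger.times, cfg.gamma_shape_clip)
    rng = np.random.default_rng(seed)
    t0 = float(trigger.times[0])
    t1 = trigger.interval[1]
    offs = _surrogate_isis(rng, shape, mean_isi, t1 - t0, cfg.sta_n_surrogates)
    traces = np.empty((cfg.sta_n_surrogates, sta.lags.size))
    for s in range(cfg.sta_n_surrogates):
        tt = t0 + np.concatenate([[0.0], offs[s][offs[s] < t1 - t0]])
        tr, n_used, _ = _sta_trace(values, signal.fs, signal.start, tt,
                                   n_lag)
        traces[s] = tr if tr is not None else np.nan
    traces = traces[~np.isnan(traces).any(axis=1)]
    if traces.shape[0] < 10 or np.allclose(traces.var(axis=0), 0):
        raise PreconditionError("surrogate STAs are degenerate")

    mean = traces.mean(axis=0)
    lo = np.percentile(traces, 2.5, axis=0)
    hi = np.percentile(traces, 97.5, axis=0)
    sta.surrogate_mean, sta.surrogate_lo, sta.surrogate_hi = mean, lo, hi
    dep = sta.mean_trace - mean

    outside = np.where(sta.mean_trace > hi, 1,
                       np.where(sta.mean_trace < lo, -1, 0))
    feats = []
    n = outside.size
    k = 0
    while k < n:
        if outside[k] == 0:
            k += 1
            continue
        j = k
        while j + 1 < n and outside[j + 1] == outside[k]:
            j += 1
        if j - k + 1 >= cfg.min_feature_bins:
            sign = int(outside[k])
            seg = sign * dep[k:j + 1]
            ext = k + int(np.argmax(seg))
            surr_stat = np.max(sign * (traces - mean[None, :]), axis=1)
            p = float((1 + np.sum(surr_stat >= sign * dep[ext]))
                      / (traces.shape[0] + 1))
            lag_lo, lag_hi = float(sta.lags[k]), float(sta.lags[j])
            position = "central" if lag_lo <= 0.0 <= lag_hi else "offset"
            signif = p < cfg.alpha_cth
            feats.append(StaFeature(
                kind="peak" if sign > 0 else "trough", position=position,
                lag=float(sta.lags[ext]), extent=(lag_lo, lag_hi),
                departure=float(dep[ext]), p_mc=p, significant=signif,
                premotor=signif and sign > 0 and position == "offset"
                and sta.lags[ext] > 0,
                inhibitory=signif and sign < 0 and position == "offset"
                and sta.lags[ext] > 0))
        k = j + 1
    sta.features = feats
    return feats
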