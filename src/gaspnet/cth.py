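"""Phase-normalized respiratory cycle-triggered histograms (CTHs).

Each spike is mapped to a normalized respiratory phase: inspiration covers
``[0, 0.5)`` and expiration ``[0.5, 1)`` regardless of their real durations,
so every cycle contributes equal visual weight per phase.  Bin rates divide
pooled spike counts by the pooled *real* time each phase bin spans, so a
homogeneous neuron yields a flat CTH even when I and E durations differ.

Respiratory modulation is assessed with two complementary tests at level
alpha (a cell is modulated if either rejects):

* **Test A** — one-way ANOVA treating cycles as replicates and phase bins
  as groups, on per-cycle per-bin firing rates.
* **Test B** — a Monte Carlo randomization: each cycle's spike phases are
  rotated by an independent uniform circular shift and the variance of the
  pooled phase-binned rate is compared with the observed value.

Modulated cells are labeled I or E by the phase half holding the peak bin,
Aug/Dec by the position of the peak within that phase (second/first half),
and phasic/tonic by whether the smoothed CTH falls essentially to zero
anywhere in the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import AnalysisConfig, PreconditionError, SpikeTrain


@dataclass
class CycleTriggeredHistogram:
    neuron_id: str
    bins_per_phase: int
    rate_per_bin: np.ndarray          # spikes/s, length 2*bins_per_phase
    n_cycles: int
    n_spikes: int
    bin_time: np.ndarray              # pooled real seconds per bin
    p_testA: float | None = None
    p_testB: float | None = None
    modulation: str | None = None     # I | E | NRM
    subtype: str | None = None        # Aug | Dec | other
    tonicity: str | None = None       # phasic | tonic
    zero_rate: bool = False

    @property
    def nbins(self) -> int:
        return 2 * self.bins_per_phase

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.nbins) + 0.5) / self.nbins

    @property
    def scaled_rate(self) -> np.ndarray:
        m = self.rate_per_bin.max()
        return self.rate_per_bin / m if m > 0 else self.rate_per_bin.copy()


def _phases_and_cycles(times, i_onset, e_onset, end):
    """Normalized phase and cycle index per spike (outside-cycle spikes
    dropped)."""
    idx = np.searchsorted(i_onset, times, side="right") - 1
    ok = idx >= 0
    safe = np.clip(idx, 0, i_onset.size - 1)
    ok &= times < end[safe]
    idx = safe[ok]
    t = times[ok]
    in_i = t < e_onset[idx]
    phase = np.where(
        in_i,
        0.5 * (t - i_onset[idx]) / (e_onset[idx] - i_onset[idx]),
        0.5 + 0.5 * (t - e_onset[idx]) / np.maximum(end[idx] - e_onset[idx],
                                                    1e-12))
    return np.clip(phase, 0.0, np.nextafter(1.0, 0.0)), idx


def _bin_times(i_onset, e_onset, end, bins_per_phase):
    """Per-cycle real seconds spanned by each of the 2*bpp phase bins."""
    di = (e_onset - i_onset) / bins_per_phase
    de = (end - e_onset) / bins_per_phase
    return np.concatenate([np.repeat(di[:, None], bins_per_phase, axis=1),
                           np.repeat(de[:, None], bins_per_phase, axis=1)],
                          axis=1)


def _count_matrix(train, cycles, bins_per_phase):
    i_on, e_on, end = cycles.i_onset, cycles.e_onset, cycles.end
    nbins = 2 * bins_per_phase
    phase, cyc = _phases_and_cycles(train.times, i_on, e_on, end)
    b = np.minimum((phase * nbins).astype(np.int64), nbins - 1)
    flat = np.bincount(cyc * nbins + b, minlength=cycles.n * nbins)
    counts = flat.reshape(cycles.n, nbins)
    times = _bin_times(i_on, e_on, end, bins_per_phase)
    return counts, times, phase, cyc


def compute_cth(train: SpikeTrain, cycles,
                bins_per_phase: int = 25) -> CycleTriggeredHistogram:
    """Pooled phase-normalized CTH over the supplied cycles."""
    if cycles.n < 1:
        raise PreconditionError("compute_cth requires >= 1 cycle")
    if bins_per_phase < 2:
        raise PreconditionError("bins_per_phase must be >= 2")
    counts, times, _, _ = _count_matrix(train, cycles, bins_per_phase)
    total_t = times.sum(axis=0)
    rate = counts.sum(axis=0) / total_t
    return CycleTriggeredHistogram(
        neuron_id=train.neuron_id, bins_per_phase=bins_per_phase,
        rate_per_bin=rate, n_cycles=cycles.n,
        n_spikes=int(counts.sum()), bin_time=total_t)


def test_modulation(train: SpikeTrain, cycles, alpha: float = 0.05,
                    n_shuffles: int = 1000, seed: int = 0,
                    bins_per_phase: int = 25):
    """Two-test respiratory-modulation screen; returns
    ``(p_testA, p_testB, modulated)``."""
    if cycles.n < 2:
        raise PreconditionError("test_modulation requires >= 2 cycles")
    counts, times, phase, cyc = _count_matrix(train, cycles, bins_per_phase)
    nbins = 2 * bins_per_phase

    rates = counts / times
    if counts.sum() == 0 or np.allclose(rates.var(axis=0), 0):
        p_a = 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p_a = stats.f_oneway(*(rates[:, b] for b in range(nbins)))
        if not np.isfinite(p_a):
            p_a = 1.0

    total_t = times.sum(axis=0)
    obs = np.var(counts.sum(axis=0) / total_t)
    rng = np.random.default_rng(seed)
    if phase.size == 0:
        p_b = 1.0
    else:
        shifts = rng.uniform(0.0, 1.0, size=(n_shuffles, cycles.n))
        new_phase = (phase[None, :] + shifts[:, cyc]) % 1.0
        b = np.minimum((new_phase * nbins).astype(np.int64), nbins - 1)
        b += nbins * np.arange(n_shuffles)[:, None]
        hist = np.bincount(b.ravel(), minlength=n_shuffles * nbins)
        surr = np.var(hist.reshape(n_shuffles, nbins) / total_t, axis=1)
        p_b = (1.0 + np.sum(surr >= obs)) / (n_shuffles + 1.0)
    modulated = (p_a < alpha) or (p_b < alpha)
    return float(p_a), float(p_b), bool(modulated)


def classify_pattern(cth: CycleTriggeredHistogram, modulated: bool,
                     config: AnalysisConfig | None = None):
    """Assign (modulation, subtype, tonicity) labels; updates ``cth`` too.

    Peak-bin ties break toward the earlier phase bin.  ``phasic`` means the
    (circularly) smoothed CTH drops below
    ``max(phasic_eps_frac * peak, phasic_eps_floor)`` somewhere.
    """
    cfg = config or AnalysisConfig()
    rate = cth.rate_per_bin
    peak = rate.max()
    if peak == 0:
        cth.modulation, cth.subtype, cth.tonicity = "NRM", "other", "phasic"
        cth.zero_rate = True
        return "NRM", "other", "phasic"

    w = max(int(cfg.cth_smooth_bins), 1)
    kernel = np.ones(w) / w
    padded = np.concatenate([rate[-(w // 2):], rate, rate[: w // 2]])
    smooth = np.convolve(padded, kernel, mode="valid")[: rate.size]
    eps = max(cfg.phasic_eps_frac * peak, cfg.phasic_eps_floor)
    tonicity = "phasic" if np.any(smooth < eps) else "tonic"

    if not modulated:
        cth.modulation, cth.subtype, cth.tonicity = "NRM", "other", tonicity
        return "NRM", "other", tonicity

    peak_bin = int(np.argmax(rate))          # argmax takes the earliest tie
    peak_phase = (peak_bin + 0.5) / rate.size
    modulation = "I" if peak_phase < 0.5 else "E"
    within = peak_phase * 2 if modulation == "I" else (peak_phase - 0.5) * 2
    subtype = "Dec" if within < 0.5 else "Aug"
    cth.modulation, cth.subtype, cth.tonicity = modulation, subtype, tonicity
    return modulation, subtype, tonicity


@dataclass
class NeuronClassification:
    neuron_id: str
    modulation: str
    subtype: str
    tonicity: str
    p_testA: float
    p_testB: float
    mean_rate: float = 0.0

    @property
    def label(self) -> str:
        if self.modulation == "NRM":
            return "NRM"
        return f"{self.modulation}-{self.subtype}"


def classify_train(train: SpikeTrain, cycles,
                   config: AnalysisConfig | None = None,
                   seed: int | None = None) -> tuple:
    """CTH + two-test screen + pattern labels for one train."""
    cfg = config or AnalysisConfig()
    cth = compute_cth(train, cycles, cfg.cth_bins_per_phase)
    p_a, p_b, modulated = test_modulation(
        train, cycles, alpha=cfg.alpha_cth, n_shuffles=cfg.cth_n_shuffles,
        seed=cfg.rng_seed if seed is None else seed,
        bins_per_phase=cfg.cth_bins_per_phase)
    cth.p_testA, cth.p_testB = p_a, p_b
    modu, sub, ton = classify_pattern(cth, modulated, cfg)
    cls = NeuronClassification(train.neuron_id, modu, sub, ton, p_a, p_b,
                               mean_rate=train.rate)
    return cth, cls
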