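"""Synthetic multi-region brainstem session generator with known ground truth.

The generator emulates the recorded preparation at three levels:

* **Respiratory-phase-locked firing**: each neuron carries a pattern class.
  Phasic cells (I-Aug, I-Dec, E-Aug, E-Dec, post-I) fire only inside their
  active phase with a raised-cosine half-wave envelope (exactly zero in the
  silent phase); tonic cells fire throughout the cycle with a full-cycle
  cosine modulation of configurable depth and peak phase; NRM cells are
  homogeneous; gasp-only cells are silent except during gasp bursts.
* **Millisecond pairwise coupling**: after each source spike the target's
  intensity is multiplied by ``strength`` on ``[latency, latency+width)``
  (multiplicative so inhibition stays a valid point process; overlapping
  effects compound).  Common-drive groups share a latent Poisson event train
  that transiently boosts every member.
* **A scripted hypoxia motor-pattern sequence**: control -> augmentation ->
  apneusis with sighs -> apnea -> gasping -> recovery, expressed in the
  respiratory cycles, the integrated phrenic envelope, and blood-pressure
  steps coincident with each gasp.

Spikes are drawn by exact thinning of the composite intensity, with one RNG
stream per neuron keyed by its id, so adding a neuron never perturbs the
spikes of unrelated neurons.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import ContinuousSignal, Session, SpikeTrain

PATTERN_CLASSES = ("I-Aug", "I-Dec", "E-Aug", "E-Dec", "post-I",
                   "tonic-I", "tonic-E", "NRM", "gasp-only")
EPOCH_CLASSES = ("control", "augmentation", "apneusis", "apnea", "gasping",
                 "recovery")


class ParameterError(ValueError):
    """A generator spec is inconsistent."""


def _stream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-entity RNG stream keyed by strings/ints."""
    h = hashlib.sha256(repr(keys).encode()).digest()
    return np.random.default_rng(
        [int(seed), int.from_bytes(h[:4], "little")])


# ---------------------------------------------------------------------------
# specs

@dataclass
class NeuronSpec:
    neuron_id: str
    region: str = "other"
    pattern_class: str = "NRM"
    base_rate: float = 10.0
    depth: float = 0.8
    phasic: bool | None = None          # None: derived from pattern_class
    gasp_participant: bool = False
    peak_phase: float | None = None     # tonic classes only

    def __post_init__(self):
        if self.pattern_class not in PATTERN_CLASSES:
            raise ParameterError(f"unknown pattern class "
                                 f"{self.pattern_class!r}")
        if self.base_rate < 0:
            raise ParameterError("base_rate must be >= 0")
        if not 0 <= self.depth <= 1:
            raise ParameterError("depth must be in [0, 1]")
        if self.phasic is None:
            self.phasic = self.pattern_class in (
                "I-Aug", "I-Dec", "E-Aug", "E-Dec", "post-I", "gasp-only")
        if self.peak_phase is None:
            self.peak_phase = {"tonic-I": 0.3, "tonic-E": 0.8}.get(
                self.pattern_class, 0.25)

    @property
    def respiratory_modulated(self) -> bool:
        return self.pattern_class not in ("NRM", "gasp-only")

    @property
    def gasp_active(self) -> bool:
        return self.gasp_participant or self.pattern_class == "gasp-only"


@dataclass
class ConnectionSpec:
    source_id: str
    target_id: str
    sign: str                            # excitatory | inhibitory
    latency: float = 0.001
    kernel_width: float = 0.002
    strength: float = 3.0

    def __post_init__(self):
        if self.source_id == self.target_id:
            raise ParameterError(f"self-connection on {self.source_id}")
        if self.latency < 0 or self.kernel_width <= 0:
            raise ParameterError("latency >= 0 and kernel_width > 0 required")
        if self.sign == "excitatory" and not self.strength > 1:
            raise ParameterError("excitatory strength must be > 1")
        if self.sign == "inhibitory" and not 0 <= self.strength < 1:
            raise ParameterError("inhibitory strength must be in [0, 1)")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ParameterError(f"unknown sign {self.sign!r}")


@dataclass
class CommonDriveSpec:
    member_ids: tuple
    rate_share: float = 4.0              # multiplicative boost while active
    kernel_width: float = 0.005
    event_rate: float = 5.0              # latent events / s

    def __post_init__(self):
        self.member_ids = tuple(self.member_ids)
        if len(set(self.member_ids)) < 2:
            raise ParameterError("common drive needs >= 2 distinct members")


@dataclass
class EpochSpec:
    kind: str
    duration: float
    amplitude_gain: float = 1.0
    frequency_gain: float = 1.0
    i_gain: float = 1.0
    sigh_every: int = 0                  # every k-th cycle is a sigh; 0 = none
    sigh_gain: float = 1.8

    def __post_init__(self):
        if self.kind not in EPOCH_CLASSES:
            raise ParameterError(f"unknown epoch class {self.kind!r}")
        if self.duration <= 0:
            raise ParameterError("epoch duration must be > 0")


@dataclass
class PatternSchedule:
    """Ordered motor-pattern epochs plus the control cycle geometry."""

    epochs: list
    i_dur: float = 1.0                   # control inspiratory duration, s
    e_dur: float = 1.5                   # control expiratory duration, s
    cycle_jitter: float = 0.03           # multiplicative SD per cycle
    gasp_interval: float = 5.0           # quasiperiodic gasp spacing, s
    gasp_interval_sd: float = 1.0
    gasp_duration: float = 0.4           # s
    gasp_tau: float = 0.15               # burst decay constant, s
    gasp_peak_rate: float = 250.0        # spikes/s at gasp onset

    def __post_init__(self):
        self.epochs = [e if isinstance(e, EpochSpec) else EpochSpec(**e)
                       for e in self.epochs]

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0],
                               np.cumsum([e.duration for e in self.epochs])])

    def epoch_intervals(self):
        b = self.boundaries
        return [(e.kind, float(b[i]), float(b[i + 1]))
                for i, e in enumerate(self.epochs)]

    def kind_at(self, t) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.boundaries, np.asarray(t),
                                      side="right") - 1,
                      0, len(self.epochs) - 1)
        kinds = np.array([e.kind for e in self.epochs])
        return kinds[idx]

    @property
    def control_window(self):
        for kind, t0, t1 in self.epoch_intervals():
            if kind == "control":
                return (t0, t1)
        return None


@dataclass
class TrueCycles:
    """Ground-truth cycle boundaries and per-cycle phrenic attributes."""

    i_onset: np.ndarray
    e_onset: np.ndarray
    end: np.ndarray
    amplitude: np.ndarray
    is_sigh: np.ndarray

    @property
    def n(self) -> int:
        return int(self.i_onset.size)


@dataclass
class GroundTruth:
    specs: list
    connections: list
    common_drives: list
    schedule: PatternSchedule
    cycles: TrueCycles
    gasp_times: np.ndarray
    bp_step_times: np.ndarray
    sigh_times: np.ndarray
    seed: int = 0

    def spec(self, neuron_id: str) -> NeuronSpec:
        for s in self.specs:
            if s.neuron_id == neuron_id:
                return s
        raise KeyError(neuron_id)

    def connected_pairs(self) -> set:
        return {frozenset((c.source_id, c.target_id))
                for c in self.connections}

    def common_drive_pairs(self) -> set:
        out = set()
        for d in self.common_drives:
            ids = list(d.member_ids)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    out.add(frozenset((a, b)))
        return out

    def pair_class(self, a: str, b: str) -> str:
        """Shared-structure class of an unordered pair.

        ``connected``: a direct coupling exists; ``common_drive``: members of
        a latent drive group; ``co_modulated``: both members share the
        respiratory drive (both phase-modulated) or the gasp drive (both
        burst at gasps) — their correlograms legitimately depart from an
        independent-ISI null; ``independent``: no shared structure.
        """
        key = frozenset((a, b))
        if key in self.connected_pairs():
            return "connected"
        if key in self.common_drive_pairs():
            return "common_drive"
        sa, sb = self.spec(a), self.spec(b)
        if sa.respiratory_modulated and sb.respiratory_modulated:
            return "co_modulated"
        if sa.gasp_active and sb.gasp_active:
            return "co_modulated"
        return "independent"

    def independent_pairs(self) -> list:
        ids = [s.neuron_id for s in self.specs]
        return [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]
                if self.pair_class(a, b) == "independent"]


# ---------------------------------------------------------------------------
# cycle / gasp scripting

def gen_cycles(schedule: PatternSchedule, seed: int):
    """Script the true respiratory cycles and gasp times for a schedule."""
    rng = _stream(seed, "cycles")
    i_on, e_on, end, amp, sigh = [], [], [], [], []
    gasps = []
    for k, (kind, t0, t1) in enumerate(schedule.epoch_intervals()):
        ep = schedule.epochs[k]
        if kind == "apnea":
            continue
        if kind == "gasping":
            gasps.extend(_gasp_times(schedule, t0, t1, rng))
            continue
        t = t0
        n_in_epoch = 0
        while True:
            jit_i = 1.0 + schedule.cycle_jitter * rng.standard_normal()
            jit_e = 1.0 + schedule.cycle_jitter * rng.standard_normal()
            di = schedule.i_dur * ep.i_gain / ep.frequency_gain * max(jit_i,
                                                                      0.5)
            de = schedule.e_dur / ep.frequency_gain * max(jit_e, 0.5)
            if t + di + de > t1:
                break
            is_sigh = (ep.sigh_every > 0
                       and n_in_epoch % ep.sigh_every == ep.sigh_every - 1)
            a = ep.sigh_gain if is_sigh else ep.amplitude_gain
            a *= 1.0 + 0.03 * rng.standard_normal()
            i_on.append(t)
            e_on.append(t + di)
            end.append(t + di + de)
            amp.append(max(a, 0.1))
            sigh.append(is_sigh)
            t += di + de
            n_in_epoch += 1
    cycles = TrueCycles(np.array(i_on), np.array(e_on), np.array(end),
                        np.array(amp), np.array(sigh, dtype=bool))
    return cycles, np.array(sorted(gasps))


def _gasp_times(schedule, t0, t1, rng):
    """Quasiperiodic gasp onsets filling (t0, t1), last gasp pinned near t1
    so the transition into the next epoch leaves no apnea-length silence."""
    span = (t1 - 2.0) - (t0 + 1.5)
    if span <= schedule.gasp_interval:
        return [t0 + 1.5, t1 - 2.0]
    ivals = []
    total = 0.0
    while total < span:
        iv = rng.normal(schedule.gasp_interval, schedule.gasp_interval_sd)
        iv = float(np.clip(iv, schedule.gasp_interval - 1.5,
                           schedule.gasp_interval + 1.5))
        ivals.append(iv)
        total += iv
    cum = np.concatenate([[0.0], np.cumsum(ivals)])
    cum *= span / cum[-1]
    return list(t0 + 1.5 + cum)


# ---------------------------------------------------------------------------
# rate profiles

class RateProfile:
    """Time-dependent firing intensity for one neuron spec.

    Inside scripted cycles the intensity follows the spec's phase profile;
    in cycle-free stretches (apnea, gasping, sub-cycle remainders) all
    phase-locked terms are suppressed: phasic cells go to zero, tonic and
    NRM cells sit at their base rate.  Gasp-active cells add a decrementing
    burst envelope (instant rise, exponential decay) at each true gasp time.
    """

    def __init__(self, spec: NeuronSpec, schedule: PatternSchedule,
                 cycles: TrueCycles, gasp_times=None):
        self.spec = spec
        self.schedule = schedule
        self.cycles = cycles
        self.gasp_times = (np.asarray(gasp_times, dtype=float)
                           if gasp_times is not None else np.empty(0))
        cyc = schedule.i_dur + schedule.e_dur
        if spec.pattern_class in ("I-Aug", "I-Dec"):
            self._A = 2.0 * spec.base_rate * cyc / schedule.i_dur
        elif spec.pattern_class in ("E-Aug", "E-Dec"):
            self._A = 2.0 * spec.base_rate * cyc / schedule.e_dur
        elif spec.pattern_class == "post-I":
            self._A = spec.base_rate * cyc / (0.25 * schedule.e_dur)
        else:
            self._A = spec.base_rate

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        spec = self.spec
        cyc = self.cycles
        out = np.zeros(t.shape)

        idx = np.searchsorted(cyc.i_onset, t, side="right") - 1
        in_cycle = (idx >= 0)
        safe = np.clip(idx, 0, max(cyc.n - 1, 0))
        if cyc.n:
            in_cycle &= t < cyc.end[safe]
        else:
            in_cycle[:] = False
        phase = np.zeros(t.shape)
        if cyc.n and in_cycle.any():
            i0 = cyc.i_onset[safe]
            e0 = cyc.e_onset[safe]
            c1 = cyc.end[safe]
            in_i = in_cycle & (t < e0)
            in_e = in_cycle & ~in_i
            phase[in_i] = 0.5 * (t[in_i] - i0[in_i]) / (e0[in_i] - i0[in_i])
            phase[in_e] = 0.5 + 0.5 * (t[in_e] - e0[in_e]) / (c1[in_e]
                                                              - e0[in_e])

        if spec.pattern_class == "NRM":
            out[:] = spec.base_rate
        elif spec.pattern_class == "gasp-only":
            out[:] = 0.0
        elif spec.pattern_class.startswith("tonic"):
            out[:] = spec.base_rate
            mod = 1.0 + spec.depth * np.cos(
                2 * np.pi * (phase - spec.peak_phase))
            out[in_cycle] = spec.base_rate * mod[in_cycle]
        else:
            g = self._half_wave(phase)
            out[in_cycle] = self._A * g[in_cycle]
            if not spec.phasic:
                # non-phasic variant keeps a floor outside the active phase
                out[in_cycle] = np.maximum(out[in_cycle],
                                           spec.base_rate
                                           * (1 - spec.depth))
        if spec.gasp_active and self.gasp_times.size:
            gi = np.searchsorted(self.gasp_times, t, side="right") - 1
            gsafe = np.clip(gi, 0, self.gasp_times.size - 1)
            dt = t - self.gasp_times[gsafe]
            in_gasp = (gi >= 0) & (dt >= 0) & (dt < self.schedule.gasp_duration)
            out[in_gasp] += (self.schedule.gasp_peak_rate
                             * np.exp(-dt[in_gasp] / self.schedule.gasp_tau))
        return out

    def _half_wave(self, phase) -> np.ndarray:
        """Raised-cosine half-wave confined to the active phase; `Aug` peaks
        at the end of the phase, `Dec` at its start."""
        cls = self.spec.pattern_class
        if cls in ("I-Aug", "I-Dec"):
            u = phase / 0.5
            active = phase < 0.5
        else:
            u = (phase - 0.5) / 0.5
            active = phase >= 0.5
        u = np.clip(u, 0.0, 1.0)
        if cls.endswith("Aug"):
            g = 0.5 * (1 - np.cos(np.pi * u))
        elif cls == "post-I":
            g = np.where(u < 0.5, 0.5 * (1 + np.cos(2 * np.pi * u)), 0.0)
        else:
            g = 0.5 * (1 + np.cos(np.pi * u))
        return np.where(active, g, 0.0)

    @property
    def max_rate(self) -> float:
        spec = self.spec
        if spec.pattern_class == "NRM":
            m = spec.base_rate
        elif spec.pattern_class == "gasp-only":
            m = 0.0
        elif spec.pattern_class.startswith("tonic"):
            m = spec.base_rate * (1 + spec.depth)
        else:
            m = self._A
        if spec.gasp_active:
            m += self.schedule.gasp_peak_rate
        return m


def gen_rate_profile(spec: NeuronSpec, schedule: PatternSchedule,
                     cycles: TrueCycles, gasp_times=None) -> RateProfile:
    return RateProfile(spec, schedule, cycles, gasp_times)


# ---------------------------------------------------------------------------
# population sampling

def _topo_order(specs, connections):
    ids = [s.neuron_id for s in specs]
    indeg = {i: 0 for i in ids}
    out_edges = {i: [] for i in ids}
    for c in connections:
        if c.source_id not in indeg or c.target_id not in indeg:
            raise ParameterError(f"connection references unknown neuron "
                                 f"{c.source_id}->{c.target_id}")
        indeg[c.target_id] += 1
        out_edges[c.source_id].append(c.target_id)
    ready = [i for i in ids if indeg[i] == 0]
    order = []
    while ready:
        n = ready.pop()
        order.append(n)
        for m in out_edges[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                ready.append(m)
    if len(order) != len(ids):
        raise ParameterError("coupling graph contains a directed cycle")
    return order


def sample_coupled_population(specs, connections, common_drives,
                              schedule: PatternSchedule, seed: int,
                              cycles: TrueCycles | None = None,
                              gasp_times=None):
    """Draw the full population by thinning; returns (trains, GroundTruth).

    Exact thinning: per neuron, homogeneous candidates at an upper bound
    computed from the profile maximum and the worst-case product of coupling
    factors, accepted with probability intensity/bound.
    """
    if len({s.neuron_id for s in specs}) != len(specs):
        raise ParameterError("neuron ids must be unique")
    if cycles is None:
        cycles, gasp_times = gen_cycles(schedule, seed)
    gasp_times = np.asarray(gasp_times if gasp_times is not None else [],
                            dtype=float)
    T = schedule.total_duration
    order = _topo_order(specs, connections)
    spec_by_id = {s.neuron_id: s for s in specs}
    in_conns = {s.neuron_id: [] for s in specs}
    for c in connections:
        in_conns[c.target_id].append(c)

    latent = {}
    for k, d in enumerate(common_drives):
        rng = _stream(seed, "drive", k)
        n = rng.poisson(d.event_rate * T)
        latent[k] = np.sort(rng.uniform(0.0, T, n))
    drives_of = {s.neuron_id: [] for s in specs}
    for k, d in enumerate(common_drives):
        for m in d.member_ids:
            if m not in drives_of:
                raise ParameterError(f"common drive references unknown "
                                     f"neuron {m}")
            drives_of[m].append(k)

    spikes: dict[str, np.ndarray] = {}
    for nid in order:
        spec = spec_by_id[nid]
        profile = RateProfile(spec, schedule, cycles, gasp_times)
        p_max = profile.max_rate
        rng = _stream(seed, "neuron", nid)
        if p_max <= 0:
            spikes[nid] = np.empty(0)
            continue
        # coupling factor F(t): piecewise constant, changepoints at the
        # window edges of every incoming source spike / latent drive event
        edges = [np.array([0.0, T])]
        logf = [np.zeros(2)]
        for c in in_conns[nid]:
            src = spikes[c.source_id]
            edges.append(src + c.latency)
            logf.append(np.full(src.size, np.log(max(c.strength, 1e-12))))
            edges.append(src + c.latency + c.kernel_width)
            logf.append(np.full(src.size, -np.log(max(c.strength, 1e-12))))
        for k in drives_of[nid]:
            d = common_drives[k]
            ev = latent[k]
            edges.append(ev)
            logf.append(np.full(ev.size, np.log(d.rate_share)))
            edges.append(ev + d.kernel_width)
            logf.append(np.full(ev.size, -np.log(d.rate_share)))
        edges = np.concatenate(edges)
        logf = np.concatenate(logf)
        srt = np.argsort(edges, kind="stable")
        edges = edges[srt]
        fvals = np.exp(np.cumsum(logf[srt]))
        # candidates at the piecewise-constant upper bound p_max * F(t),
        # accepted with profile(t)/p_max (exact thinning)
        widths = np.diff(edges)
        inside = (edges[:-1] < T) & (widths > 0)
        means = p_max * fvals[:-1] * widths
        means[~inside] = 0.0
        counts = rng.poisson(means)
        piece = np.repeat(np.arange(widths.size), counts)
        cand = edges[piece] + rng.uniform(0.0, 1.0, piece.size) * widths[piece]
        cand = np.sort(cand[(cand >= 0) & (cand < T)])
        keep = rng.uniform(0.0, 1.0, cand.size) < profile(cand) / p_max
        spikes[nid] = cand[keep]

    trains = [SpikeTrain(neuron_id=s.neuron_id, times=spikes[s.neuron_id],
                         interval=(0.0, T), region=s.region)
              for s in specs]
    sigh_times = (cycles.e_onset[cycles.is_sigh]
                  if cycles.n else np.empty(0))
    truth = GroundTruth(specs=list(specs), connections=list(connections),
                        common_drives=list(common_drives), schedule=schedule,
                        cycles=cycles, gasp_times=gasp_times,
                        bp_step_times=gasp_times.copy(),
                        sigh_times=sigh_times, seed=seed)
    return trains, truth


# ---------------------------------------------------------------------------
# continuous signals

def gen_phrenic_and_bp(schedule: PatternSchedule, cycles: TrueCycles,
                       gasp_times, fs: float, seed: int,
                       bp_step_height: float = 10.0):
    """Integrated phrenic envelope and arterial blood pressure traces.

    Phrenic bursts step to 30% of their amplitude at inspiratory onset and
    ramp to the peak at the I->E transition (an augmenting envelope with a
    sharp onset, as in an integrated nerve recording), then decay quickly in
    expiration.  Gasps are decrementing: an instant rise followed by
    exponential decay.  Blood pressure carries a step of the configured
    height at each gasp, a slow drift, and measurement noise.
    """
    if fs < 100:
        raise ParameterError("fs must be >= 100 Hz")
    gasp_times = np.asarray(gasp_times if gasp_times is not None else [],
                            dtype=float)
    T = schedule.total_duration
    n = int(round(T * fs))
    t = np.arange(n) / fs
    rng = _stream(seed, "phrenic")
    phr = np.zeros(n)

    idx = np.searchsorted(cycles.i_onset, t, side="right") - 1
    safe = np.clip(idx, 0, max(cycles.n - 1, 0))
    if cycles.n:
        i0, e0, c1 = (cycles.i_onset[safe], cycles.e_onset[safe],
                      cycles.end[safe])
        amp = cycles.amplitude[safe]
        in_i = (idx >= 0) & (t >= i0) & (t < e0)
        in_e = (idx >= 0) & (t >= e0) & (t < c1)
        v = np.zeros(n)
        v[in_i] = (t[in_i] - i0[in_i]) / (e0[in_i] - i0[in_i])
        phr[in_i] = amp[in_i] * (0.3 + 0.7 * v[in_i])
        phr[in_e] = amp[in_e] * np.exp(-(t[in_e] - e0[in_e]) / 0.01)
    for tg in gasp_times:
        m = (t >= tg) & (t < tg + schedule.gasp_duration + 0.3)
        phr[m] = np.maximum(phr[m], 1.4 * np.exp(-(t[m] - tg) / 0.12))
    phr *= 1.0 + 0.02 * rng.standard_normal(n)
    phr += 0.01 * rng.standard_normal(n)
    phrenic = ContinuousSignal("phrenic_integrated", fs, 0.0, phr)

    rng_bp = _stream(seed, "bp")
    bp = np.full(n, 100.0)
    for tg in gasp_times:
        m = t >= tg
        bp[m] += bp_step_height * np.exp(-(t[m] - tg) / 60.0)
    bp += 2.0 * np.sin(2 * np.pi * t / 300.0)
    bp += 0.8 * rng_bp.standard_normal(n)
    blood = ContinuousSignal("blood_pressure", fs, 0.0, bp)
    return phrenic, blood


def _gen_etco2(schedule: PatternSchedule, fs: float, seed: int):
    T = schedule.total_duration
    n = int(round(T * fs))
    t = np.arange(n) / fs
    kinds = schedule.kind_at(t)
    base = np.where(np.isin(kinds, ("control", "recovery")), 38.0, 26.0)
    # smooth the transition with a 10 s moving average
    w = max(int(10 * fs), 1)
    kernel = np.ones(w) / w
    base = np.convolve(base, kernel, mode="same")
    rng = _stream(seed, "etco2")
    return ContinuousSignal("etco2", fs, 0.0,
                            base + 0.5 * rng.standard_normal(n))


# ---------------------------------------------------------------------------
# scenario assembly

@dataclass
class ScenarioConfig:
    name: str
    schedule: PatternSchedule
    neurons: list
    connections: list = field(default_factory=list)
    common_drives: list = field(default_factory=list)
    fs: float = 200.0
    bp_step_height: float = 10.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(name=d["name"],
                   schedule=PatternSchedule(**d["schedule"]),
                   neurons=[NeuronSpec(**n) for n in d["neurons"]],
                   connections=[ConnectionSpec(**c)
                                for c in d.get("connections", [])],
                   common_drives=[CommonDriveSpec(**c)
                                  for c in d.get("common_drives", [])],
                   fs=d.get("fs", 200.0),
                   bp_step_height=d.get("bp_step_height", 10.0))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=list)
            fh.write("\n")


def gen_session(scenario: ScenarioConfig, seed: int):
    """Compose cycles, spikes and signals into a validated Session + truth."""
    if scenario.schedule.control_window is None:
        raise ParameterError("schedule has no control epoch; control "
                             "statistics are required downstream")
    cycles, gasp_times = gen_cycles(scenario.schedule, seed)
    trains, truth = sample_coupled_population(
        scenario.neurons, scenario.connections, scenario.common_drives,
        scenario.schedule, seed, cycles=cycles, gasp_times=gasp_times)
    phrenic, bp = gen_phrenic_and_bp(scenario.schedule, cycles, gasp_times,
                                     scenario.fs, seed,
                                     scenario.bp_step_height)
    etco2 = _gen_etco2(scenario.schedule, scenario.fs, seed)
    session = Session(
        trains=trains,
        signals={s.name: s for s in (phrenic, bp, etco2)},
        control_window=scenario.schedule.control_window,
        metadata={"scenario": scenario.name, "seed": seed})
    return session, truth


def hypoxia_default() -> ScenarioConfig:
    """The bundled hypoxia exposure scenario: 20 neurons, 12 couplings,
    control -> augmentation -> apneusis+sighs -> apnea -> gasping -> recovery.

    The 12 benchmark couplings link weakly modulated and non-modulated
    neurons so their offset correlogram features stand on a locally flat
    background; strongly phase-locked and gasp-bursting cells are present
    for the rate-pattern analyses and share drive (respiratory or gasp) with
    each other rather than being independent controls (see docs/methods.md).
    """
    schedule = PatternSchedule(epochs=[
        EpochSpec("control", 300.0),
        EpochSpec("augmentation", 60.0, amplitude_gain=1.4,
                  frequency_gain=1.4),
        EpochSpec("apneusis", 60.0, i_gain=2.5, sigh_every=4),
        EpochSpec("apnea", 30.0),
        EpochSpec("gasping", 60.0),
        EpochSpec("recovery", 120.0),
    ])
    N = NeuronSpec
    neurons = [
        N("V01", "VRC", "I-Aug", 10.0, 1.0, gasp_participant=True),
        N("V02", "VRC", "E-Dec", 10.0, 1.0),
        N("V03", "VRC", "tonic-I", 10.0, 0.15, peak_phase=0.375),
        N("V04", "VRC", "tonic-E", 10.0, 0.15, peak_phase=0.875),
        N("V05", "VRC", "NRM", 12.0, 0.0),
        N("V06", "VRC", "NRM", 10.0, 0.0),
        N("V07", "VRC", "NRM", 10.0, 0.0),
        N("V08", "VRC", "gasp-only", 0.0, 0.0),
        N("R01", "raphe", "tonic-E", 10.0, 0.15, peak_phase=0.625),
        N("R02", "raphe", "tonic-I", 10.0, 0.15, peak_phase=0.3),
        N("R03", "raphe", "NRM", 8.0, 0.0, gasp_participant=True),
        N("R04", "raphe", "NRM", 12.0, 0.0),
        N("R05", "raphe", "NRM", 10.0, 0.0),
        N("R06", "raphe", "NRM", 10.0, 0.0),
        N("P01", "pons", "tonic-I", 10.0, 0.15, peak_phase=0.4,
          gasp_participant=True),
        N("P02", "pons", "tonic-E", 10.0, 0.15, peak_phase=0.7),
        N("P03", "pons", "NRM", 10.0, 0.0),
        N("P04", "pons", "NRM", 15.0, 0.0),
        N("P05", "pons", "NRM", 10.0, 0.0),
        N("P06", "pons", "NRM", 12.0, 0.0),
    ]
    C = ConnectionSpec
    connections = [
        C("V03", "V05", "excitatory", 0.001, 0.002, 3.0),
        C("V04", "V03", "inhibitory", 0.0015, 0.002, 0.15),
        C("V05", "R04", "excitatory", 0.002, 0.002, 2.5),
        C("R01", "V03", "inhibitory", 0.002, 0.002, 0.15),
        C("R02", "P03", "excitatory", 0.003, 0.002, 3.0),
        C("P02", "V04", "inhibitory", 0.002, 0.002, 0.2),
        C("P04", "P05", "excitatory", 0.001, 0.002, 2.5),
        C("R04", "P05", "excitatory", 0.002, 0.003, 2.5),
        C("V03", "R03", "excitatory", 0.0015, 0.002, 3.0),
        C("P03", "R04", "inhibitory", 0.0025, 0.002, 0.2),
        C("R05", "R01", "inhibitory", 0.002, 0.002, 0.2),
        C("P06", "R06", "excitatory", 0.002, 0.002, 2.8),
    ]
    drives = [CommonDriveSpec(("R06", "P05"), rate_share=6.0,
                              kernel_width=0.005, event_rate=8.0)]
    return ScenarioConfig(name="hypoxia_default", schedule=schedule,
                          neurons=neurons, connections=connections,
                          common_drives=drives)
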