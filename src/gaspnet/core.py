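"""Domain types and delimited-text I/O for multi-neuron recording sessions.

A session couples spike-time tables (one sorted train per neuron, with a
brainstem region label) with uniformly sampled continuous traces (integrated
phrenic nerve activity, arterial blood pressure, end-tidal CO2).  Times are
seconds throughout; intervals are half-open ``[t0, t1)``.

The interchange format is plain comma-separated text so fixtures stay
language-agnostic and diffable:

* ``spikes.csv`` — columns ``neuron_id,time_s``
* ``neurons.csv`` — columns ``neuron_id,region``
* ``<name>.signal.csv`` — header line ``# fs=<Hz> start=<s>``, one sample/row
* ``session.json`` — interval, control window, free-form metadata
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

REGIONS = ("VRC", "raphe", "pons", "other")
SIGNAL_NAMES = ("phrenic_integrated", "blood_pressure", "etco2",
                "tracheal_pressure", "other")


class ValidationError(ValueError):
    """A session object violates a structural invariant."""


class FormatError(ValueError):
    """An interchange file cannot be parsed."""


class PreconditionError(ValueError):
    """An operation was called on inputs that do not satisfy its contract."""


@dataclass
class SpikeTrain:
    """One neuron's sorted spike times on a half-open recording interval."""

    neuron_id: str
    times: np.ndarray
    interval: tuple[float, float]
    region: str = "other"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.interval = (float(self.interval[0]), float(self.interval[1]))

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]

    @property
    def rate(self) -> float:
        return self.n_spikes / self.duration if self.duration > 0 else math.nan

    def violations(self) -> list[str]:
        out = []
        t0, t1 = self.interval
        if not t0 < t1:
            out.append(f"{self.neuron_id}: interval not increasing ({t0}, {t1})")
        if self.region not in REGIONS:
            out.append(f"{self.neuron_id}: unknown region {self.region!r}")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                out.append(f"times not increasing for {self.neuron_id}")
            if self.times[0] < t0 or self.times[-1] >= t1:
                out.append(f"{self.neuron_id}: spike outside interval")
            if not np.all(np.isfinite(self.times)):
                out.append(f"{self.neuron_id}: non-finite spike time")
        return out


@dataclass
class ContinuousSignal:
    """Uniformly sampled trace: ``samples[i]`` is at ``start + i / fs``."""

    name: str
    fs: float
    start: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.fs = float(self.fs)
        self.start = float(self.start)

    @property
    def end(self) -> float:
        return self.start + self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.start + np.arange(self.samples.size) / self.fs

    def index_of(self, t) -> np.ndarray:
        """Nearest sample index for time(s) ``t`` (no bounds check)."""
        return np.rint((np.asarray(t) - self.start) * self.fs).astype(np.int64)

    def violations(self) -> list[str]:
        out = []
        if not self.fs > 0:
            out.append(f"signal {self.name}: fs must be > 0")
        if not np.all(np.isfinite(self.samples)):
            out.append(f"signal {self.name}: non-finite samples")
        return out


@dataclass
class Session:
    """A set of simultaneously recorded trains plus continuous signals."""

    trains: list[SpikeTrain]
    signals: dict[str, ContinuousSignal] = field(default_factory=dict)
    control_window: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def neuron_ids(self) -> list[str]:
        return [t.neuron_id for t in self.trains]

    def train(self, neuron_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.neuron_id == neuron_id:
                return t
        raise KeyError(neuron_id)

    @property
    def interval(self) -> tuple[float, float]:
        if not self.trains:
            sigs = list(self.signals.values())
            if sigs:
                return (min(s.start for s in sigs), max(s.end for s in sigs))
            return (0.0, 0.0)
        return (min(t.interval[0] for t in self.trains),
                max(t.interval[1] for t in self.trains))


@dataclass
class AnalysisConfig:
    """All tunable thresholds for the analysis stages, with package defaults.

    Defaults follow the printed operating points where stated (two-test level
    0.05, detectability-index cutoff 3.0, FDR level 0.05); the rest are
    documented operational definitions (see docs/methods.md).
    """

    # cycle-triggered histograms
    cth_bins_per_phase: int = 25
    alpha_cth: float = 0.05
    cth_n_shuffles: int = 1000
    phasic_eps_frac: float = 0.05
    phasic_eps_floor: float = 0.5       # spikes/s
    cth_smooth_bins: int = 3
    # cross-correlogram screening
    corr_bin_width: float = 0.0005      # s
    corr_window: float = 0.05           # s, half width
    n_surrogates: int = 1000
    di_threshold: float = 3.0
    fdr_q: float = 0.05
    gamma_shape_clip: tuple[float, float] = (0.05, 100.0)
    min_feature_bins: int = 2
    # respiratory pattern segmentation
    smooth_width: float = 0.05          # s, moving-average for phrenic
    cycle_k_on: float = 0.2
    cycle_k_off: float = 0.1
    augment_z: float = 2.0
    augment_n_consec: int = 3
    apneusis_factor: float = 2.0
    sigh_factor: float = 1.5
    apnea_cycle_factor: float = 2.0
    apnea_floor: float = 5.0            # s
    gasp_tpk_frac: float = 0.25
    bp_step_height: float = 5.0         # mmHg
    bp_step_window: float = 2.0         # s
    bp_median_width: float = 0.5        # s
    gasp_sync_window: float = 0.5       # s, half width around gasp onset
    gasp_sync_rate_factor: float = 3.0
    gasp_sync_min_frac: float = 0.5
    # spike-triggered averaging
    sta_window: float = 0.1             # s, half width
    sta_n_surrogates: int = 200
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("cth_bins_per_phase", "cth_n_shuffles", "n_surrogates",
                     "augment_n_consec", "min_feature_bins",
                     "sta_n_surrogates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("alpha_cth", "fdr_q"):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"{name} must be in (0, 1)")
        for name in ("corr_bin_width", "corr_window", "smooth_width",
                     "bp_step_window", "sta_window"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")

    def replace(self, **kw) -> "AnalysisConfig":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return AnalysisConfig(**d)


# ---------------------------------------------------------------------------
# validation

def validate_session(session: Session) -> list[str]:
    """Report every invariant violation; an empty list means a valid session.

    Never raises: the report names the offending entity and rule.
    """
    report: list[str] = []
    seen = set()
    for tr in session.trains:
        if tr.neuron_id in seen:
            report.append(f"neuron_id not unique: {tr.neuron_id}")
        seen.add(tr.neuron_id)
        report.extend(tr.violations())
    for sig in session.signals.values():
        report.extend(sig.violations())
    if session.control_window is not None:
        c0, c1 = session.control_window
        if not c0 < c1:
            report.append("control_window not increasing")
        for tr in session.trains:
            if c0 < tr.interval[0] or c1 > tr.interval[1]:
                report.append(
                    f"control_window outside interval of {tr.neuron_id}")
    return report


# ---------------------------------------------------------------------------
# readers / writers

def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def read_signal(path) -> ContinuousSignal:
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise FormatError(f"{path}: missing '# fs=... start=...' header")
    kv = dict(tok.split("=", 1) for tok in header.lstrip("# ").split()
              if "=" in tok)
    if "fs" not in kv:
        raise FormatError(f"{path}: missing fs in header")
    name = os.path.basename(str(path))
    if name.endswith(".signal.csv"):
        name = name[: -len(".signal.csv")]
    samples = pd.read_csv(path, comment="#", header=None,
                          float_precision="round_trip").to_numpy().ravel()
    return ContinuousSignal(name=name, fs=float(kv["fs"]),
                            start=float(kv.get("start", 0.0)), samples=samples)


def write_signal(sig: ContinuousSignal, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={_fmt(sig.fs)} start={_fmt(sig.start)}\n")
        fh.writelines(_fmt(v) + "\n" for v in sig.samples)


def read_session(spike_path, signal_paths=(), meta_path=None,
                 neurons_path=None) -> Session:
    """Load and validate a session from the delimited-text interchange files.

    Raises :class:`ValidationError` naming the offending neuron on any
    invariant violation; nothing is silently dropped or reordered.
    """
    spikes = pd.read_csv(spike_path, float_precision="round_trip")
    if not {"neuron_id", "time_s"} <= set(spikes.columns):
        raise FormatError(f"{spike_path}: need columns neuron_id,time_s")
    regions: dict[str, str] = {}
    if neurons_path is not None:
        ndf = pd.read_csv(neurons_path)
        regions = dict(zip(ndf["neuron_id"].astype(str), ndf["region"]))
    meta = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    interval = tuple(meta.get("interval", (0.0, math.inf)))
    control = meta.get("control_window")
    trains = []
    seen = set()
    for nid, grp in spikes.groupby("neuron_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=np.float64)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"times not increasing for {nid}")
        tr = SpikeTrain(neuron_id=str(nid), times=times, interval=interval,
                        region=regions.get(str(nid), "other"))
        trains.append(tr)
        seen.add(str(nid))
    # neurons listed in the metadata but silent in the record
    for nid in sorted(set(regions) - seen):
        trains.append(SpikeTrain(neuron_id=nid, times=np.empty(0),
                                 interval=interval, region=regions[nid]))
    trains.sort(key=lambda t: t.neuron_id)
    signals = {}
    for p in signal_paths:
        sig = read_signal(p)
        signals[sig.name] = sig
    sess = Session(trains=trains, signals=signals,
                   control_window=tuple(control) if control else None,
                   metadata=meta.get("metadata", {}))
    bad = validate_session(sess)
    if bad:
        raise ValidationError("; ".join(bad))
    return sess


def write_session(session: Session, out_dir) -> list[str]:
    """Write the interchange files; returns the manifest of paths written.

    ``read_session(write_session(s))`` reproduces ``s`` exactly — times are
    stored with 17 significant digits, which round-trips IEEE doubles.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = []

    spike_path = os.path.join(out_dir, "spikes.csv")
    with open(spike_path, "w") as fh:
        fh.write("neuron_id,time_s\n")
        for tr in sorted(session.trains, key=lambda t: t.neuron_id):
            fh.writelines(f"{tr.neuron_id},{_fmt(t)}\n" for t in tr.times)
    manifest.append(spike_path)

    neurons_path = os.path.join(out_dir, "neurons.csv")
    with open(neurons_path, "w") as fh:
        fh.write("neuron_id,region\n")
        for tr in sorted(session.trains, key=lambda t: t.neuron_id):
            fh.write(f"{tr.neuron_id},{tr.region}\n")
    manifest.append(neurons_path)

    for name in sorted(session.signals):
        p = os.path.join(out_dir, f"{name}.signal.csv")
        write_signal(session.signals[name], p)
        manifest.append(p)

    meta_path = os.path.join(out_dir, "session.json")
    t0, t1 = session.interval
    if not math.isfinite(t1):      # unbounded interval: derive from data
        t1 = max((float(t.times[-1]) for t in session.trains
                  if t.times.size), default=0.0) + 1.0
    if not math.isfinite(t0):
        t0 = 0.0
    meta = {"interval": [t0, t1],
            "control_window": list(session.control_window)
            if session.control_window else None,
            "metadata": session.metadata}
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest.append(meta_path)
    return manifest


def read_session_dir(in_dir) -> Session:
    """Convenience inverse of :func:`write_session`."""
    sig_paths = [os.path.join(in_dir, f) for f in sorted(os.listdir(in_dir))
                 if f.endswith(".signal.csv")]
    return read_session(os.path.join(in_dir, "spikes.csv"), sig_paths,
                        os.path.join(in_dir, "session.json"),
                        neurons_path=os.path.join(in_dir, "neurons.csv"))
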