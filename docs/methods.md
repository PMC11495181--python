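# Methods

`gaspnet` implements, as a tested pipeline over synthetic ground-truth data,
the spike-train analyses used to characterize how the raphe–pontomedullary
respiratory network reconfigures during severe hypoxia: respiratory
cycle-triggered histogram (CTH) classification, motor-pattern segmentation
of the integrated phrenic signal, pairwise cross-correlogram screening
against gamma-ISI surrogate nulls with false-discovery-rate control,
spike-triggered averaging, and assembly of directed correlation feature
maps.  Because the underlying in vivo recordings are not publicly
deposited, every stage is validated by parameter and structure recovery on
a synthetic population whose ground truth is known exactly.

## Domain model and units

All times are seconds (float64); lags and latencies are seconds internally
and printed as milliseconds only for display.  Recording intervals are
half-open `[t0, t1)`; a spike exactly at `t1` is invalid.  The interchange
format is delimited text (spikes.csv, neurons.csv, per-signal CSV with an
`# fs=... start=...` header, session.json) written with 17 significant
digits so that write→read round-trips IEEE doubles exactly.

## Synthetic session generator

The generator is the package's study-condition definition, not a test
convenience; its defaults were chosen once, at design time, to emulate a
decerebrate, vagotomized, artificially ventilated cat preparation at
desk-compute scale.

**Respiratory cycles.** Control cycles have inspiratory (I) duration 1.0 s
and expiratory (E) duration 1.5 s with 3% multiplicative jitter per cycle —
a eupneic rhythm of ~24 cycles/min.  The scripted motor-pattern schedule of
the bundled `hypoxia_default` scenario is control 300 s → augmentation 60 s
(amplitude ×1.4 and frequency ×1.4) → apneusis 60 s (I duration ×2.5, with
an augmented breath every 4th cycle at amplitude ×1.8) → apnea 30 s →
gasping 60 s → recovery 120 s, mirroring a transient 5% O₂ exposure of a
few hundred seconds.

**Firing patterns.** Phasic cells (I-Aug, I-Dec, E-Aug, E-Dec, post-I) use
raised-cosine half-waves confined to their active phase — exactly zero
elsewhere — with the peak at the end (Aug) or start (Dec) of the phase and
the amplitude normalized so the cycle-mean rate equals `base_rate`
(default 10 spikes/s).  Tonic cells fire throughout the cycle with a
full-cycle cosine modulation `base·(1 + depth·cos 2π(φ − φ_peak))`; the
peak phase realizes the I/E and Aug/Dec labels.  NRM cells are homogeneous
Poisson; gasp-only cells are silent outside gasp bursts.  During apnea and
gasping all phase-locked terms are suppressed (phasic → 0, tonic/NRM →
base).  Gasp-participating cells add a decrementing burst at each gasp:
instant rise to 250 spikes/s with exponential decay (τ = 0.15 s) over a
0.4 s envelope — roughly 30 extra spikes per gasp, which is what makes a
cell detectably gasp-synchronous under the ×3-median-rate criterion below.
Gasps are quasiperiodic at 5 ± 1 s intervals, rescaled to pin the last
gasp near the epoch end so the gasping→recovery transition never contains
an apnea-length silence the schedule did not script.

**Coupling.** After each source spike the target intensity is multiplied
by `strength` on `[latency, latency + width)`; overlapping effects
compound.  Multiplicative coupling keeps inhibition bounded at zero, i.e.
the process remains a valid inhomogeneous Poisson process.  Common-drive
groups share a latent Poisson event train (default 8 events/s) that boosts
every member ×6 for 5 ms — calibrated so a 600 s record yields a central
correlogram peak of ~4σ.  Spikes are drawn by exact thinning: the bound is
piecewise constant (`profile_max ×` the running product of coupling
factors, with changepoints at window edges), candidates are drawn from the
bound and accepted with probability `profile/profile_max`.  No
discrete-time approximation is involved; the empirical rate of a constant-
intensity cell is within 2% of nominal, and the measured excess of target
spikes in the coupling window matches `N_src · r_tgt · width ·
(strength − 1)` within Monte Carlo error (both are regression tests).
Coupling graphs must be acyclic; each neuron draws from its own RNG stream
keyed by (seed, neuron id), so adding a neuron never perturbs the spikes
of neurons not downstream of it.

**Signals.** The integrated phrenic envelope steps to 30% of the cycle
amplitude at I onset and ramps linearly to the peak at the I→E transition
(sharp onset, augmenting profile, rapid expiratory decay τ = 10 ms): onset
and offset crossings are then localizable to within the 50 ms smoothing
window.  Gasps are decrementing envelopes (instant rise ×1.4, τ = 0.12 s).
Blood pressure is 100 mmHg baseline plus a 10 mmHg step at each gasp
(decaying with τ = 60 s), a slow drift, and 0.8 mmHg noise.

**The benchmark topology.**  The 20-neuron `hypoxia_default` population
carries 12 injected couplings (6 excitatory ×2.5–3.0, 6 inhibitory
×0.15–0.2; latencies 1–3 ms, widths 2–3 ms), including two disinhibition
chains (A ⊣ B ⊣ C), one latent common-drive pair, strongly phase-locked
cells of every CTH class, and four gasp-participating cells across the
three regions.  The couplings deliberately link weakly modulated
(depth 0.15) and non-modulated cells: two strongly co-modulated neurons
share the respiratory drive itself, and against an i.i.d.-ISI surrogate
null that shared slow drive is a genuine, detectable central-peak feature
(exactly the shared-source reading of central peaks in correlogram
analysis).  Ground truth therefore classifies every pair as `connected`,
`common_drive`, `co_modulated` (both respiratory-modulated, or both
gasp-bursting), or `independent`; false-positive control is asserted on
the `independent` class, the only pairs with no shared structure at all.

## Cycle detection and motor-pattern segmentation

Cycles are detected on a 50 ms moving-average copy of the phrenic signal
with hysteresis thresholds derived from the control window: θ_on =
baseline + 0.2·(peak − baseline), θ_off at 0.1, with baseline/peak the
5th/95th percentiles.  A flat signal returns an empty cycle set with a
warning flag.

Epoch labels are explicit operational rules for pattern classes that are
assigned by expert inspection on real records; every threshold is in
`AnalysisConfig`:

* **augmentation** — amplitude or frequency above control mean + 2 SD for
  ≥ 3 consecutive cycles;
* **apneusis** — I duration > 2× control median;
* **sigh** (augmented breath, an event not an epoch) — peak > 1.5× control
  median amplitude, late in I (time-to-peak > half the burst);
* **apnea** — no burst for longer than max(2× control median cycle, 5 s),
  measured from the last burst's off-transition; the epoch boundary is
  placed where the last expiration would have ended;
* **gasp** — a burst during/after apnea with time-to-peak < 0.25× burst
  duration and duration < control median I (decrementing shape separates
  gasps from sighs, whose peak is late);
* **gasping** — the span of ≥ 2 consecutive gasps; the quasiperiodic
  silences between gasps belong to the gasping epoch, not apnea;
* **recovery** — control-like cycles after the perturbation.

Epochs tile the analyzed window without overlap.  Blood-pressure steps are
sustained rises > 5 mmHg within 2 s on a 0.5 s median-filtered trace; a
gasp "coincides" with a step within ±2 s.  A neuron is gasp-synchronous if
its rate within ±0.5 s of ≥ 50% of gasp onsets exceeds 3× its
session-median (1 s-binned) rate; for a control-silent cell the median is
zero, so any gasp-locked firing flags it — reproducing the observation
that cells bursting during gasps need not be inspiratory during control.

## CTH classification

Spikes map to normalized phase (I → [0, 0.5), E → [0.5, 1), linear within
each phase regardless of real durations), 25 bins per phase.  Bin rates
divide pooled counts by pooled *real* bin time, so a homogeneous cell is
flat even with unequal I/E durations.  Modulation is declared when either
of two complementary tests rejects at α = 0.05:

* **Test A** — one-way ANOVA with cycles as replicates and phase bins as
  groups, on per-cycle per-bin rates;
* **Test B** — Monte Carlo randomization: each cycle's phases are rotated
  by an independent uniform circular shift; the statistic is the variance
  of the pooled phase-binned **rate** (not raw counts — with unequal real
  phase durations the raw-count variance has a deterministic component
  under the null and the rotation test would reject always); p = (1 + #{
  surrogate ≥ observed}) / (n + 1).

Under homogeneous Poisson firing on symmetric cycles both tests are
calibrated (type-I error within the binomial CI of 0.05 at 400
simulations); with asymmetric cycles Test B is conservative.  Modulated
cells take the phase half of the peak bin (ties toward the earlier bin),
Aug/Dec from the peak's position within that phase, and phasic/tonic from
whether the 3-bin circularly smoothed CTH falls below
max(0.05·peak, 0.5 spikes/s) anywhere.  On the recovery benchmark (200
cells, depth 0.8, 100 cycles) ≥ 95% of cells recover their full generating
label; with depth 0.15 (the weakly modulated cells of the benchmark
topology) detection is intentionally borderline.

## Correlogram screening

Correlograms use 0.5 ms bins over ±50 ms (half-open bins; positive lag =
target after reference), resolving 1–5 ms synaptic-latency features.
Counts are exact (a compiled two-pointer merge, verified bin-for-bin
against exhaustive pair enumeration).

The null model replaces **both** trains with surrogates built from i.i.d.
gamma ISIs — shape fitted per train by the method of moments
(`mean²/var`, clipped to [0.05, 100]), scale matching the mean ISI, laid
end-to-end from the original first spike — destroying all correlation
while preserving rate and ISI dispersion.  1000 surrogate pairs (200 in
the scaled-down null calibration) give per-bin mean and 2.5/97.5%
pointwise bands.  A candidate feature is a run of ≥ 2 consecutive bins
outside the band with the same sign.  Its Monte Carlo p-value compares the
extremum departure against each surrogate correlogram's own maximum
departure over all bins in that sign (a max-statistic correction within
the pair).  The detectability index divides the extremum departure by the
standard deviation of out-of-feature residuals (counts − surrogate mean
outside every candidate extent) — the noise of the observed correlogram,
not the surrogate SD.  DI ≥ 3 gates significance (the cutoff is stated
both as > 3.0 and as ≥ 3 in the source analyses; ≥ is adopted).

Across a session, each pair's p-value is the minimum over its features
(1.0 with none) and Benjamini–Hochberg is applied across pairs at
q = 0.05; a feature is significant iff its pair survives BH **and**
DI ≥ 3.  Offset features are canonicalized to positive lag by swapping the
pair orientation.  Surrogates are generated once per train and shared
across that train's pairs (within a pair the null is exact; across pairs
this induces a mild positive dependence of the kind BH tolerates).  With
Monte Carlo p-values the attainable floor is 1/(n_surrogates + 1); BH can
only reject when enough pairs reach small p, which makes the procedure
conservative on null-only sessions — the FDR benchmark (50 replicates ×
100 independent Poisson pairs) realizes a false-positive replicate
fraction at or near zero against the 0.05 bound.

## Spike-triggered averages

STAs of the full-wave-rectified phrenic signal (baseline = median, since
nerve records carry offsets) use a ±100 ms window.  Bands come from STAs
triggered on gamma-ISI surrogate trains (200 by default); features are
runs outside the pointwise bands with the same max-statistic p-value as
the correlogram screen.  A significant offset peak at positive lag flags a
premotor relation; an offset trough flags functional inhibition of the
downstream drive.

## Feature maps

Offset peaks become directed excitatory edges source→target, offset
troughs directed inhibitory edges; central peaks/troughs become undirected
shared-drive / shared-opposite-influence edges on the sorted pair.
Unobserved common sources are not synthesized as nodes.  Multiple
significant features of one pair produce multiple edges.  Summaries report
per-region recorded/connected counts and fractions, edge counts by sign,
and the disinhibition-motif count (# directed chains A ⊣ B ⊣ C with
A ≠ C).  The firing-rate heat-map matrix scales each neuron's binned rate
to its own maximum.

## Problem sizes and numerical choices

The shipped benchmarks run at desk scale, chosen as the smallest sizes at
which each operating characteristic is measurable: FDR calibration at 50
replicates × 100 pairs × 200 surrogates; connection recovery on the 630 s
20-neuron scenario at 1000 surrogates × 10 seeds; CTH recovery on 200
cells × 100 cycles; type-I calibration at 400 simulations.  Ties for a
correlogram extremum break toward the smallest |lag|; ties for the CTH
peak toward the earlier bin.  Monte Carlo p-values use the add-one
convention.  Degenerate pairs (zero surrogate variance) abort feature
detection for that pair with a diagnostic and are listed in the screening
report rather than raising.

## What passing tests do and do not show

The generator produces inhomogeneous-Poisson populations with ideal-shaped
bursts, stationary control statistics, and exactly scripted epochs.  Real
records add spike-sorting errors, slow nonstationarity (drift, blood-gas
state), oscillatory co-modulation at frequencies between cycle and
synaptic timescales, and bursting (non-renewal) ISI structure that a
single gamma shape does not capture.  Recovery results here therefore
validate the implementation and the internal consistency of the
procedure's operating characteristics — not the biological sensitivity or
specificity of correlational connectivity inference on in vivo data.  In
particular, strongly co-modulated pairs are *correctly* detected as
shared-drive features against the i.i.d.-ISI null; on real data the
analyst must read central features through that lens, exactly as the
original analyses do.

## Known limitations

* The CTH modulation tests stand in for the lab-specific test battery the
  source analyses cite; they are one parametric and one randomization test
  with the stated level, calibrated here, but not the original code.
* Gasp interval/duration constants are qualitative (no quantitative values
  are published for the preparation); they are config-exposed.
* Per-feature (rather than per-pair) BH is available in concept but the
  per-pair minimum is the implemented default; post-inspiratory cells are
  labeled E-Dec rather than given a separate class.
* The pipeline screens the whole recording by default; `screen_epochs`
  restricts screening to labeled epoch classes when a per-state analysis
  is wanted.
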