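import numpy as np
import pytest

from gaspnet import (AnalysisConfig, ContinuousSignal, EpochSpec,
                     PatternSchedule, classify_epochs,
                     detect_bp_steps_and_sync, detect_cycles, detect_gasps,
                     gen_phrenic_and_bp, gen_session, hypoxia_default)
from gaspnet.core import PreconditionError
from gaspnet.synth import gen_cycles


def control_phrenic(seed=0, duration=120.0, fs=200.0):
    sched = PatternSchedule(epochs=[EpochSpec("control", duration)])
    cycles, gasps = gen_cycles(sched, seed)
    phr, bp = gen_phrenic_and_bp(sched, cycles, gasps, fs, seed)
    return sched, cycles, phr, bp


class TestDetectCycles:
    def test_recovers_true_boundaries(self):
        _, truth, phr, _ = control_phrenic(seed=1)
        det = detect_cycles(phr, control_window=(0.0, 120.0))
        assert det.n == truth.n
        assert np.max(np.abs(det.i_onset - truth.i_onset)) < 0.05
        assert np.max(np.abs(det.e_onset - truth.e_onset)) < 0.05

    def test_flat_signal_empty_with_flag(self):
        sig = ContinuousSignal("phrenic_integrated", 200.0, 0.0,
                               np.zeros(2000))
        det = detect_cycles(sig)
        assert det.n == 0 and det.flat_signal

    def test_single_square_burst(self):
        t = np.arange(0, 5, 1 / 200.0)
        x = np.where((t >= 1.0) & (t < 2.0), 1.0, 0.0)
        det = detect_cycles(ContinuousSignal("phrenic_integrated", 200.0,
                                             0.0, x))
        assert det.n == 1
        assert det.i_onset[0] == pytest.approx(1.0, abs=0.06)
        assert det.e_onset[0] == pytest.approx(2.0, abs=0.06)


class TestClassifyEpochs:
    def test_recovers_scheduled_sequence(self, default_run, segmented):
        _, truth = default_run
        epochs = segmented["epochs"]
        truth_iv = truth.schedule.epoch_intervals()
        assert [e.kind for e in epochs] == [k for k, _, _ in truth_iv]
        for e, (kind, t0, t1) in zip(epochs, truth_iv):
            local = 2.5 if kind in ("control", "augmentation",
                                    "recovery") else 5.6
            assert abs(e.t0 - t0) <= local, (kind, e.t0, t0)

    def test_control_only_single_epoch(self):
        _, _, phr, _ = control_phrenic(seed=2)
        cycles = detect_cycles(phr, control_window=(0.0, 120.0))
        epochs, sighs = classify_epochs(phr, cycles, (0.0, 120.0))
        assert [e.kind for e in epochs] == ["control"]
        assert sighs == []

    def test_sigh_events_recovered(self):
        sched = PatternSchedule(epochs=[
            EpochSpec("control", 120.0),
            EpochSpec("apneusis", 50.0, i_gain=2.5, sigh_every=4)])
        cycles, gasps = gen_cycles(sched, seed=5)
        phr, _ = gen_phrenic_and_bp(sched, cycles, gasps, 200.0, seed=5)
        det = detect_cycles(phr, control_window=(0.0, 120.0))
        epochs, sighs = classify_epochs(phr, det, (0.0, 120.0))
        truth_sighs = cycles.e_onset[cycles.is_sigh]
        assert len(sighs) == truth_sighs.size
        for ev in sighs:
            assert np.min(np.abs(truth_sighs - ev.time)) < 0.2

    def test_too_few_control_cycles_rejected(self):
        _, _, phr, _ = control_phrenic(seed=3, duration=60.0)
        cycles = detect_cycles(phr, control_window=(0.0, 60.0))
        with pytest.raises(PreconditionError, match="control"):
            classify_epochs(phr, cycles, (0.0, 10.0))

    def test_epochs_tile_without_overlap(self, segmented):
        epochs = segmented["epochs"]
        for a, b in zip(epochs[:-1], epochs[1:]):
            assert a.t1 == pytest.approx(b.t0)
        assert epochs[0].t0 <= 0.0 and epochs[-1].t1 >= 620.0

    def test_robust_to_small_noise(self, default_run):
        session, truth = default_run
        phr = session.signals["phrenic_integrated"]
        noisy = ContinuousSignal(
            phr.name, phr.fs, phr.start,
            phr.samples + 0.05 * np.random.default_rng(0)
            .standard_normal(phr.samples.size))
        cycles = detect_cycles(noisy, control_window=session.control_window)
        epochs, _ = classify_epochs(noisy, cycles, session.control_window)
        assert [e.kind for e in epochs] == \
            [e.kind for e in truth.schedule.epochs]


class TestDetectGasps:
    def test_recovers_generated_gasps(self, default_run, segmented):
        _, truth = default_run
        gasps = segmented["gasps"]
        assert len(gasps) == truth.gasp_times.size
        errs = np.abs(np.array([g.time for g in gasps])
                      - truth.gasp_times)
        assert errs.max() < 0.1

    def test_no_gasps_in_control(self):
        _, _, phr, _ = control_phrenic(seed=6)
        cycles = detect_cycles(phr, control_window=(0.0, 120.0))
        epochs, _ = classify_epochs(phr, cycles, (0.0, 120.0))
        assert detect_gasps(phr, epochs, cycles=cycles,
                            control_window=(0.0, 120.0)) == []

    def test_augmented_breath_is_not_gasp(self):
        """Sighs (late peak, long rise) during depression must not be
        counted as gasps even when apnea follows."""
        sched = PatternSchedule(epochs=[
            EpochSpec("control", 120.0),
            EpochSpec("apneusis", 40.0, i_gain=2.5, sigh_every=3),
            EpochSpec("apnea", 20.0),
            EpochSpec("gasping", 30.0)])
        cycles, gasps_true = gen_cycles(sched, seed=7)
        phr, _ = gen_phrenic_and_bp(sched, cycles, gasps_true, 200.0,
                                    seed=7)
        det = detect_cycles(phr, control_window=(0.0, 120.0))
        epochs, _ = classify_epochs(phr, det, (0.0, 120.0))
        gasps = detect_gasps(phr, epochs, cycles=det,
                             control_window=(0.0, 120.0))
        # every detected gasp matches a true gasp, none matches a sigh
        for g in gasps:
            assert np.min(np.abs(gasps_true - g.time)) < 0.2

    def test_specificity_control_only(self):
        """No false gasp events across 100 control-only simulations."""
        total = 0
        for seed in range(100):
            _, _, phr, _ = control_phrenic(seed=seed, duration=60.0,
                                           fs=200.0)
            cycles = detect_cycles(phr, control_window=(0.0, 60.0))
            epochs, _ = classify_epochs(phr, cycles, (0.0, 60.0))
            total += len(detect_gasps(phr, epochs, cycles=cycles,
                                      control_window=(0.0, 60.0)))
        assert total == 0


class TestBpStepsAndSync:
    def test_coincidence_matches_truth(self, default_run, segmented):
        session, truth = default_run
        steps, sync, coinc = detect_bp_steps_and_sync(
            session.signals["blood_pressure"], segmented["gasps"],
            session.trains)
        assert coinc == truth.gasp_times.size
        assert len(steps) == truth.bp_step_times.size

    def test_sync_table_is_exactly_the_participants(self, default_run,
                                                    segmented):
        session, truth = default_run
        _, sync, _ = detect_bp_steps_and_sync(
            session.signals["blood_pressure"], segmented["gasps"],
            session.trains,
            classes={"V08": "NRM"})
        expected = {s.neuron_id for s in truth.specs if s.gasp_active}
        assert set(sync.neuron_id) == expected
        # control-silent gasp-only cell is flagged with its (non-modulated)
        # control class
        assert sync.set_index("neuron_id").loc["V08", "control_class"] \
            == "NRM"

    def test_no_gasps_empty_table(self, default_run):
        session, _ = default_run
        steps, sync, coinc = detect_bp_steps_and_sync(
            session.signals["blood_pressure"], [], session.trains)
        assert len(sync) == 0 and coinc == 0
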