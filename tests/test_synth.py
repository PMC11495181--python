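import numpy as np
import pytest

from gaspnet import (CommonDriveSpec, ConnectionSpec, EpochSpec, NeuronSpec,
                     PatternSchedule, gen_cycles, gen_rate_profile,
                     gen_phrenic_and_bp, gen_session, hypoxia_default,
                     sample_coupled_population)
from gaspnet.synth import ParameterError


def control_schedule(duration=120.0):
    return PatternSchedule(epochs=[EpochSpec("control", duration)])


@pytest.fixture(scope="module")
def control_cycles():
    sched = control_schedule(300.0)
    cycles, gasps = gen_cycles(sched, seed=0)
    return sched, cycles


class TestRateProfile:
    def test_i_aug_rises_through_inspiration(self, control_cycles):
        sched, cycles = control_cycles
        spec = NeuronSpec("n", "VRC", "I-Aug", base_rate=10.0, depth=1.0)
        prof = gen_rate_profile(spec, sched, cycles)
        i0, e0 = cycles.i_onset[0], cycles.e_onset[0]
        t = np.linspace(i0, e0 - 1e-6, 50)
        r = prof(t)
        assert r[0] == pytest.approx(0.0, abs=1e-6)
        assert np.argmax(r) > 25                       # peak in 2nd half of I
        assert np.all(np.diff(r) >= -1e-9)             # augmenting
        # silent in expiration for a phasic cell
        te = np.linspace(e0 + 1e-3, cycles.end[0] - 1e-3, 20)
        assert np.all(prof(te) == 0.0)

    def test_i_dec_peaks_first_half(self, control_cycles):
        sched, cycles = control_cycles
        prof = gen_rate_profile(NeuronSpec("n", "VRC", "I-Dec"), sched,
                                cycles)
        i0, e0 = cycles.i_onset[0], cycles.e_onset[0]
        t = np.linspace(i0, e0 - 1e-6, 50)
        assert np.argmax(prof(t)) < 25

    def test_nrm_constant(self, control_cycles):
        sched, cycles = control_cycles
        prof = gen_rate_profile(
            NeuronSpec("n", "pons", "NRM", base_rate=7.0, depth=0.0),
            sched, cycles)
        t = np.linspace(0, 299, 1000)
        np.testing.assert_allclose(prof(t), 7.0)

    def test_mean_rate_near_base(self, control_cycles):
        sched, cycles = control_cycles
        for cls in ("I-Aug", "E-Dec", "post-I", "tonic-I"):
            prof = gen_rate_profile(NeuronSpec("n", "VRC", cls, 10.0, 0.3),
                                    sched, cycles)
            t = np.arange(0, 300, 0.002)
            assert prof(t).mean() == pytest.approx(10.0, rel=0.06), cls

    def test_gasp_only_silent_in_control(self):
        sched = PatternSchedule(epochs=[
            EpochSpec("control", 60.0), EpochSpec("apnea", 10.0),
            EpochSpec("gasping", 30.0)])
        cycles, gasps = gen_cycles(sched, seed=1)
        prof = gen_rate_profile(NeuronSpec("g", "VRC", "gasp-only"), sched,
                                cycles, gasp_times=gasps)
        t = np.arange(0, 60, 0.01)
        assert np.all(prof(t) == 0.0)
        tg = np.arange(70, 100, 0.01)
        r = prof(tg)
        assert r.max() > 0
        # positive only inside gasp envelopes
        on = r > 0
        for ti in tg[on]:
            d = ti - gasps[gasps <= ti]
            assert d.size and d.min() < sched.gasp_duration + 1e-9

    def test_unknown_class_rejected(self):
        with pytest.raises(ParameterError, match="pattern class"):
            NeuronSpec("n", "VRC", "bursting")


class TestSampling:
    def test_uncoupled_poisson_counts(self):
        sched = control_schedule(300.0)
        specs = [NeuronSpec(f"n{i}", "other", "NRM", 10.0, 0.0)
                 for i in range(2)]
        trains, truth = sample_coupled_population(specs, [], [], sched,
                                                  seed=3)
        for tr in trains:
            assert abs(tr.n_spikes - 3000) < 4 * np.sqrt(3000)

    def test_thinning_rate_accuracy(self):
        """Empirical rate of a constant-intensity spec within 2% of nominal
        over 100 runs."""
        sched = control_schedule(50.0)
        spec = [NeuronSpec("n", "other", "NRM", 20.0, 0.0)]
        total = sum(
            sample_coupled_population(spec, [], [], sched, seed=s)[0][0]
            .n_spikes for s in range(100))
        assert total / (100 * 50.0) == pytest.approx(20.0, rel=0.02)

    def test_coupling_calibration(self):
        """Excess target spikes in the coupling window match
        N_src * r_tgt * width * (strength - 1) within 3 Monte Carlo SDs."""
        sched = control_schedule(300.0)
        specs = [NeuronSpec("s", "other", "NRM", 10.0, 0.0),
                 NeuronSpec("t", "other", "NRM", 10.0, 0.0)]
        conn = [ConnectionSpec("s", "t", "excitatory", 0.001, 0.002, 3.0)]
        obs, pred, var = 0.0, 0.0, 0.0
        for s in range(20):
            trains, _ = sample_coupled_population(specs, conn, [], sched,
                                                  seed=100 + s)
            src, tgt = trains[0].times, trains[1].times
            hi = np.searchsorted(tgt, src + 0.003)
            lo = np.searchsorted(tgt, src + 0.001)
            inside = (hi - lo).sum()
            bg = src.size * 10.0 * 0.002
            obs += inside - bg
            pred += src.size * 10.0 * 0.002 * (3.0 - 1.0)
            var += src.size * 10.0 * 0.002 * 3.0
        assert abs(obs - pred) < 3 * np.sqrt(var)

    def test_determinism(self):
        sc = hypoxia_default()
        s1, t1 = gen_session(sc, 9)
        s2, t2 = gen_session(sc, 9)
        for a, b in zip(s1.trains, s2.trains):
            np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(
            s1.signals["phrenic_integrated"].samples,
            s2.signals["phrenic_integrated"].samples)

    def test_seed_changes_spikes_not_topology(self):
        sc = hypoxia_default()
        s1, t1 = gen_session(sc, 1)
        s2, t2 = gen_session(sc, 2)
        assert not np.array_equal(s1.trains[0].times, s2.trains[0].times)
        assert [(c.source_id, c.target_id) for c in t1.connections] == \
            [(c.source_id, c.target_id) for c in t2.connections]

    def test_adding_neuron_preserves_other_streams(self):
        sched = control_schedule(60.0)
        base = [NeuronSpec("a", "other", "NRM", 10.0, 0.0)]
        extra = base + [NeuronSpec("b", "other", "NRM", 10.0, 0.0)]
        t1, _ = sample_coupled_population(base, [], [], sched, seed=4)
        t2, _ = sample_coupled_population(extra, [], [], sched, seed=4)
        np.testing.assert_array_equal(t1[0].times, t2[0].times)

    def test_self_connection_rejected(self):
        with pytest.raises(ParameterError, match="self-connection"):
            ConnectionSpec("a", "a", "excitatory")

    def test_cyclic_graph_rejected(self):
        sched = control_schedule(10.0)
        specs = [NeuronSpec("a", "other", "NRM"),
                 NeuronSpec("b", "other", "NRM")]
        conn = [ConnectionSpec("a", "b", "excitatory"),
                ConnectionSpec("b", "a", "excitatory")]
        with pytest.raises(ParameterError, match="cycle"):
            sample_coupled_population(specs, conn, [], sched, seed=0)

    def test_empty_connection_list(self):
        sc = hypoxia_default()
        sc.connections = []
        sc.common_drives = []
        _, truth = gen_session(sc, 1)
        assert truth.connections == []


class TestSignals:
    def test_control_phrenic_stationary(self):
        sched = control_schedule(30.0)
        cycles, gasps = gen_cycles(sched, seed=2)
        phr, bp = gen_phrenic_and_bp(sched, cycles, gasps, 200.0, seed=2)
        t = phr.times()
        peaks = [phr.samples[(t >= a) & (t < b)].max()
                 for a, b in zip(cycles.i_onset, cycles.e_onset)]
        assert len(peaks) >= 10
        assert np.std(peaks) / np.mean(peaks) < 0.1

    def test_gasping_bursts_and_bp_steps(self):
        sched = PatternSchedule(epochs=[
            EpochSpec("control", 60.0), EpochSpec("apnea", 10.0),
            EpochSpec("gasping", 25.0)])
        cycles, gasps = gen_cycles(sched, seed=3)
        phr, bp = gen_phrenic_and_bp(sched, cycles, gasps, 200.0, seed=3,
                                     bp_step_height=10.0)
        t = phr.times()
        for tg in gasps:
            seg = phr.samples[(t >= tg) & (t < tg + 0.35)]
            assert seg.max() > 1.2                      # burst present
            assert np.argmax(seg) < 0.25 * seg.size     # decrementing
            before = bp.samples[(t >= tg - 3) & (t < tg - 1)].mean()
            after = bp.samples[(t >= tg + 1) & (t < tg + 3)].mean()
            assert after - before > 5.0                 # BP step

    def test_apnea_epoch_flat(self):
        sched = PatternSchedule(epochs=[EpochSpec("control", 60.0),
                                        EpochSpec("apnea", 20.0)])
        cycles, gasps = gen_cycles(sched, seed=4)
        phr, _ = gen_phrenic_and_bp(sched, cycles, gasps, 200.0, seed=4)
        t = phr.times()
        assert phr.samples[(t > 61) & (t < 79)].max() < 0.15

    def test_low_fs_rejected(self):
        sched = control_schedule(10.0)
        cycles, gasps = gen_cycles(sched, seed=0)
        with pytest.raises(ParameterError, match="fs"):
            gen_phrenic_and_bp(sched, cycles, gasps, 50.0, seed=0)


class TestScenario:
    def test_default_scenario_valid(self, default_run):
        from gaspnet import validate_session
        session, truth = default_run
        assert validate_session(session) == []
        assert len(session.trains) == 20
        assert len(truth.connections) == 12

    def test_no_control_epoch_rejected(self):
        sc = hypoxia_default()
        sc.schedule = PatternSchedule(epochs=[EpochSpec("apnea", 30.0)])
        with pytest.raises(ParameterError, match="control"):
            gen_session(sc, 1)

    def test_truth_pair_classes(self, default_run):
        _, truth = default_run
        assert truth.pair_class("V03", "V05") == "connected"
        assert truth.pair_class("R06", "P05") == "common_drive"
        assert truth.pair_class("V01", "V02") == "co_modulated"
        assert truth.pair_class("V01", "R03") == "co_modulated"  # gasp pair
        assert truth.pair_class("V05", "P04") == "independent"

    def test_scenario_dict_roundtrip(self):
        sc = hypoxia_default()
        back = type(sc).from_dict(sc.to_dict())
        assert [n.neuron_id for n in back.neurons] == \
            [n.neuron_id for n in sc.neurons]
        assert back.schedule.total_duration == sc.schedule.total_duration
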