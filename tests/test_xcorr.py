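import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaspnet import (AnalysisConfig, CommonDriveSpec, ConnectionSpec,
                     EpochSpec, NeuronSpec, PatternSchedule, SpikeTrain,
                     compute_correlogram, detect_features,
                     fit_gamma_and_surrogates, fit_gamma_shape,
                     sample_coupled_population, screen_pairs)
from gaspnet.core import PreconditionError

from conftest import poisson_train


def coupled_pair(strength=3.0, latency=0.001, width=0.002, duration=600.0,
                 seed=42, rate=10.0):
    specs = [NeuronSpec("ref", "other", "NRM", rate, 0.0),
             NeuronSpec("tgt", "other", "NRM", rate, 0.0)]
    conn = [ConnectionSpec("ref", "tgt", "excitatory", latency, width,
                           strength)]
    sched = PatternSchedule(epochs=[EpochSpec("control", duration)])
    trains, _ = sample_coupled_population(specs, conn, [], sched, seed)
    return trains


class TestComputeCorrelogram:
    def test_pure_shift_single_bin(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 100, 300))
        # keep ISIs longer than the window so only shifted partners pair up
        t = t[np.concatenate([[True], np.diff(t) > 0.05])]
        ref = SpikeTrain("r", t, (0, 101))
        tgt = SpikeTrain("t", t + 0.0052, (0, 101))
        c = compute_correlogram(ref, tgt, 0.001, 0.02)
        nz = np.flatnonzero(c.counts)
        assert nz.tolist() == [25]
        assert c.lags[25] == pytest.approx(0.0055)
        assert c.counts[25] == ref.n_spikes

    def test_two_single_spike_trains(self):
        ref = SpikeTrain("r", np.array([1.0]), (0, 2))
        tgt = SpikeTrain("t", np.array([1.0023]), (0, 2))
        c = compute_correlogram(ref, tgt, 0.001, 0.02)
        assert c.counts.sum() == 1
        assert c.lags[np.argmax(c.counts)] == pytest.approx(0.0025)

    def test_flat_for_independent_poisson(self):
        a = poisson_train(10.0, 600.0, 1, "a")
        b = poisson_train(10.0, 600.0, 2, "b")
        c = compute_correlogram(a, b, 0.001, 0.02)
        expect = a.n_spikes * 10.0 * 0.001
        assert np.all(np.abs(c.counts - expect) < 4 * np.sqrt(expect))

    def test_empty_ref_rejected(self):
        ref = SpikeTrain("r", np.empty(0), (0, 1))
        tgt = SpikeTrain("t", np.array([0.5]), (0, 1))
        with pytest.raises(PreconditionError, match="r"):
            compute_correlogram(ref, tgt)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.integers(1, 100), st.integers(1, 100))
    def test_conservation_against_bruteforce(self, seed, na, nb):
        """Binned counts equal exhaustive pair enumeration, exactly."""
        rng = np.random.default_rng(seed)
        a = SpikeTrain("a", np.sort(rng.uniform(0, 5, na)), (0, 5))
        b = SpikeTrain("b", np.sort(rng.uniform(0, 5, nb)), (0, 5))
        c = compute_correlogram(a, b, 0.0005, 0.05)
        lags = (b.times[None, :] - a.times[:, None]).ravel()
        lags = lags[(lags >= c.edges[0]) & (lags < c.edges[-1])]
        brute = np.bincount(((lags - c.edges[0]) / c.bin_width).astype(int),
                            minlength=c.nbins)
        np.testing.assert_array_equal(c.counts, brute)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_symmetry(self, seed):
        """corr(a,b) at +lag equals corr(b,a) at -lag, bin-exactly."""
        rng = np.random.default_rng(seed)
        a = SpikeTrain("a", np.sort(rng.uniform(0, 20, 150)), (0, 20))
        b = SpikeTrain("b", np.sort(rng.uniform(0, 20, 150)), (0, 20))
        ab = compute_correlogram(a, b, 0.001, 0.02)
        ba = compute_correlogram(b, a, 0.001, 0.02)
        # bin [lo, hi) at +lag mirrors to [-hi, -lo) at -lag
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])


class TestGammaSurrogates:
    def test_poisson_shape_is_one(self):
        tr = poisson_train(10.0, 500.0, 3)
        shape, _ = fit_gamma_shape(tr.times)
        assert shape == pytest.approx(1.0, abs=0.1)

    def test_regular_train_clips_high(self):
        tr = SpikeTrain("n", np.arange(0, 100, 0.1), (0, 100))
        shape, _ = fit_gamma_shape(tr.times)
        assert shape == 100.0

    def test_shape_four_recovered(self):
        rng = np.random.default_rng(7)
        isi = rng.gamma(4.0, 0.025, 5000)
        tr = SpikeTrain("n", np.cumsum(isi), (0.0, float(isi.sum() + 1)))
        shape, _ = fit_gamma_shape(tr.times)
        assert 3.6 <= shape <= 4.4

    def test_too_few_spikes_rejected(self):
        tr = SpikeTrain("n", np.array([1.0]), (0, 10))
        with pytest.raises(PreconditionError):
            fit_gamma_shape(tr.times)

    def test_surrogates_preserve_rate(self):
        tr = poisson_train(10.0, 300.0, 4)
        _, surr = fit_gamma_and_surrogates(tr, n_surrogates=100, seed=0)
        rates = [s.n_spikes / 300.0 for s in surr]
        assert np.mean(rates) == pytest.approx(10.0, rel=0.05)

    def test_surrogates_reproducible(self):
        tr = poisson_train(10.0, 100.0, 5)
        _, s1 = fit_gamma_and_surrogates(tr, 5, seed=9)
        _, s2 = fit_gamma_and_surrogates(tr, 5, seed=9)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.times, b.times)


class TestDetectFeatures:
    def test_offset_peak_on_strong_excitation(self):
        trains = coupled_pair()
        cfg = AnalysisConfig(n_surrogates=200)
        edges, _ = screen_pairs(trains, cfg, seed=0)
        sig = edges[edges.significant]
        assert len(sig) >= 1
        top = sig.loc[sig.di.idxmax()]
        assert top.kind == "peak" and top.position == "offset"
        assert 0.0 < top.extremum_lag_s <= 0.004
        assert top.di >= 3.0

    def test_central_peak_on_common_drive(self):
        specs = [NeuronSpec("a", "other", "NRM", 10.0, 0.0),
                 NeuronSpec("b", "other", "NRM", 10.0, 0.0)]
        drive = [CommonDriveSpec(("a", "b"), rate_share=6.0,
                                 kernel_width=0.005, event_rate=8.0)]
        sched = PatternSchedule(epochs=[EpochSpec("control", 600.0)])
        trains, _ = sample_coupled_population(specs, [], drive, sched, 8)
        cfg = AnalysisConfig(n_surrogates=200)
        edges, _ = screen_pairs(trains, cfg, seed=8)
        sig = edges[edges.significant]
        assert len(sig) >= 1
        assert (sig.position == "central").any()

    def test_explicit_surrogate_api(self):
        trains = coupled_pair(duration=300.0)
        corr = compute_correlogram(trains[0], trains[1])
        _, sr = fit_gamma_and_surrogates(trains[0], 100, seed=1)
        _, st_ = fit_gamma_and_surrogates(trains[1], 100, seed=2)
        feats = detect_features(corr, sr, st_, AnalysisConfig())
        assert corr.surrogate_mean is not None
        assert any(f.kind == "peak" and f.position == "offset"
                   for f in feats)

    def test_di_monotone_in_strength(self):
        """Median DI does not decrease as injected strength grows."""
        medians = []
        for strength in (1.5, 2.0, 3.0):
            dis = []
            for s in range(50):
                trains = coupled_pair(strength=strength, duration=300.0,
                                      seed=1000 + s)
                cfg = AnalysisConfig(n_surrogates=100)
                edges, _ = screen_pairs(trains, cfg, seed=s)
                off = edges[(edges.kind == "peak")
                            & (edges.position == "offset")
                            & (edges.extremum_lag_s > 0)
                            & (edges.extremum_lag_s <= 0.004)]
                dis.append(off.di.max() if len(off) else 0.0)
            medians.append(np.median(dis))
        assert medians[0] <= medians[1] + 0.5
        assert medians[1] <= medians[2] + 0.5
        assert medians[2] > medians[0]


class TestScreenPairs:
    def test_single_train_empty(self):
        edges, rep = screen_pairs([poisson_train(10, 60, 0)],
                                  AnalysisConfig(n_surrogates=100))
        assert len(edges) == 0 and rep["n_pairs_assessed"] == 0

    def test_pair_count_is_combinatorial(self):
        trains = [poisson_train(10.0, 60.0, s, f"n{s}") for s in range(6)]
        _, rep = screen_pairs(trains, AnalysisConfig(n_surrogates=100),
                              seed=0)
        assert rep["n_pairs_assessed"] == 15

    def test_degenerate_train_skipped_not_fatal(self):
        trains = [poisson_train(10.0, 60.0, 1, "a"),
                  SpikeTrain("b", np.array([1.0]), (0.0, 60.0))]
        edges, rep = screen_pairs(trains, AnalysisConfig(n_surrogates=100))
        assert rep["n_pairs_skipped"] == 1
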