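"""Functionality criteria: attractor detection, volleys, separatrix, AI stats."""

import numpy as np
import pytest

from spikecomp.criteria import (StateSpacePoint, ai_statistics,
                                classify_propagation, detect_attractors,
                                dwell_and_competition, fit_separatrix,
                                measure_pulse_packet, rate_spectrum,
                                spike_filter, up_down_voltage_profile)
from spikecomp.simulator import VoltageTraces, poisson_sources
from spikecomp.spikes import SpikeData


class TestDetectAttractors:
    def test_single_high_rate_episode(self):
        rng = np.random.default_rng(0)
        trains = {}
        for i in range(30):     # pattern 0 fires 40 Hz in [1000, 2000]
            trains[i] = np.sort(rng.uniform(1000, 2000, size=40))
        for i in range(30, 60):  # pattern 1 silent
            trains[i] = np.sort(rng.uniform(0, 4000, size=2))
        sd = SpikeData(trains, {"PYR": (0, 60)}, 4000.0)
        eps = detect_attractors(sd, {0: range(30), 1: range(30, 60)})
        assert len(eps) == 1
        assert eps[0].pattern == 0
        assert eps[0].t_start == pytest.approx(1000, abs=60)
        assert eps[0].t_end == pytest.approx(2000, abs=60)

    def test_equal_low_rates_give_no_episodes(self):
        rng = np.random.default_rng(1)
        trains = {i: np.sort(rng.uniform(0, 3000, size=6)) for i in range(60)}
        sd = SpikeData(trains, {"PYR": (0, 60)}, 3000.0)
        eps = detect_attractors(sd, {0: range(30), 1: range(30, 60)})
        assert eps == []

    def test_silence_gives_empty_list_full_competition(self):
        sd = SpikeData({}, {"PYR": (0, 60)}, 2000.0)
        eps = detect_attractors(sd, {0: range(30), 1: range(30, 60)})
        dwells, comp = dwell_and_competition(eps, 2000.0)
        assert eps == [] and comp == 2000.0

    def test_three_scripted_episodes_recovered(self, scripted_attractor_raster):
        sd, patterns, episodes = scripted_attractor_raster
        eps = detect_attractors(sd, patterns)
        assert len(eps) == 3
        for found, (pid, a, b) in zip(eps, episodes):
            assert found.pattern == pid
            assert found.t_start == pytest.approx(a, abs=50)
            assert found.t_end == pytest.approx(b, abs=50)

    def test_time_conservation(self, scripted_attractor_raster):
        sd, patterns, _ = scripted_attractor_raster
        eps = detect_attractors(sd, patterns)
        dwells, comp = dwell_and_competition(eps, sd.duration)
        assert dwells.sum() + comp == pytest.approx(sd.duration)

    def test_episodes_never_overlap(self, scripted_attractor_raster):
        sd, patterns, _ = scripted_attractor_raster
        eps = sorted(detect_attractors(sd, patterns), key=lambda e: e.t_start)
        for a, b in zip(eps, eps[1:]):
            assert a.t_end <= b.t_start + 1e-9


class TestUpDownProfile:
    @staticmethod
    def _traces(depolarized, episodes, n=6, duration=4000.0):
        t = np.arange(0.0, duration, 1.0)
        traces = {}
        for i in range(n):
            v = np.full(t.size, -70.0)
            if depolarized:
                home = 0 if i < n // 2 else 1
                for ep in episodes:
                    if ep.pattern == home:
                        v[(t >= ep.t_start) & (t < ep.t_end)] = -65.0
            traces[i] = v
        return VoltageTraces(t, traces)

    def test_constant_voltage_gives_flat_curves(self):
        from spikecomp.criteria import AttractorEpisode
        eps = [AttractorEpisode(0, 1000.0, 1400.0)]
        traces = self._traces(False, eps)
        prof = up_down_voltage_profile(traces, eps, {i: 0 for i in range(6)})
        inner = ~np.isnan(prof["up"])
        assert np.allclose(prof["up"][inner], -70.0)

    def test_scripted_depolarization_plateau(self):
        from spikecomp.criteria import AttractorEpisode
        eps = [AttractorEpisode(0, 1000.0, 1400.0),
               AttractorEpisode(1, 2000.0, 2400.0)]
        traces = self._traces(True, eps)
        parent = {i: (0 if i < 3 else 1) for i in range(6)}
        prof = up_down_voltage_profile(traces, eps, parent)
        axis = prof["axis"]
        inside = (axis > 0.1) & (axis < 0.9)
        assert np.nanmean(prof["up"][inside]) == pytest.approx(-65.0, abs=0.3)
        assert np.nanmean(prof["down"][inside]) == pytest.approx(-70.0, abs=0.3)
        # UP - DOWN plateau difference equals the scripted 5 mV
        assert (np.nanmean(prof["up"][inside])
                - np.nanmean(prof["down"][inside])) == pytest.approx(5.0, abs=0.5)

    def test_no_episodes_is_an_error(self):
        traces = self._traces(False, [])
        with pytest.raises(ValueError):
            up_down_voltage_profile(traces, [], {})


class TestRateSpectrum:
    def test_poisson_population_has_flat_spectrum(self):
        sd = poisson_sources(50, 20.0, 20000.0, seed=2)
        spec = rate_spectrum(sd, "poisson")
        smooth = spec["psd_smooth"]
        sel = spec["freqs"] > 2.0
        assert smooth[sel].max() < 3.0 * np.median(smooth[sel])

    def test_sinusoidal_rate_peak_recovered(self):
        rng = np.random.default_rng(3)
        t, out = 0.0, []
        while t < 20000.0:
            t += rng.exponential(1.0 / 0.8)
            if t < 20000.0 and rng.random() < 0.5 * (1 + np.sin(2 * np.pi * 25e-3 * t)):
                out.append(t)
        sd = SpikeData({0: np.asarray(out)}, {"P": (0, 1)}, 20000.0)
        spec = rate_spectrum(sd, "P")
        assert spec["peak"] == pytest.approx(25.0, abs=1.0)

    def test_peak_robust_to_binning(self):
        rng = np.random.default_rng(4)
        t, out = 0.0, []
        while t < 20000.0:
            t += rng.exponential(1.0 / 0.8)
            if t < 20000.0 and rng.random() < 0.5 * (1 + np.sin(2 * np.pi * 30e-3 * t)):
                out.append(t)
        sd = SpikeData({0: np.asarray(out)}, {"P": (0, 1)}, 20000.0)
        p1 = rate_spectrum(sd, "P", bin_ms=1.0)["peak"]
        p2 = rate_spectrum(sd, "P", bin_ms=2.0)["peak"]
        assert abs(p1 - p2) <= 2.0

    def test_silent_data_flagged(self):
        sd = SpikeData({}, {"P": (0, 10)}, 1000.0)
        assert rate_spectrum(sd, "P")["peak"] is None


class TestPulsePacketMeasure:
    def test_full_activation(self):
        trains = {i: np.array([100.0 + 0.01 * i]) for i in range(100)}
        sd = SpikeData(trains, {"RS": (0, 100)}, 200.0)
        pt = measure_pulse_packet(sd, "RS", (90.0, 110.0))
        assert pt.a == pytest.approx(1.0)

    def test_simultaneous_spikes_zero_sigma(self):
        trains = {i: np.array([100.0]) for i in range(50)}
        sd = SpikeData(trains, {"RS": (0, 50)}, 200.0)
        pt = measure_pulse_packet(sd, "RS", (90.0, 110.0))
        assert pt.sigma == 0.0

    def test_silent_group_flagged(self):
        sd = SpikeData({}, {"RS": (0, 100)}, 200.0)
        pt = measure_pulse_packet(sd, "RS", (90.0, 110.0))
        assert pt.a == 0.0 and np.isnan(pt.sigma) and not pt.fired

    def test_scripted_gaussian_volley_sigma(self):
        rng = np.random.default_rng(5)
        times = rng.normal(100.0, 2.0, size=300)
        trains = {i: np.sort(times[3 * i:3 * i + 3]) for i in range(100)}
        sd = SpikeData(trains, {"RS": (0, 100)}, 200.0)
        pt = measure_pulse_packet(sd, "RS", (80.0, 120.0))
        assert pt.sigma == pytest.approx(2.0, abs=0.25)

    def test_classification_boundary_closed(self):
        assert not classify_propagation(StateSpacePoint(0.0, np.nan))
        assert classify_propagation(StateSpacePoint(1.0, 0.1))
        assert classify_propagation(StateSpacePoint(0.5, 0.1), threshold=0.5)


class TestSpikeFilter:
    def test_isolated_spike_removed_volley_kept(self):
        trains = {0: np.array([50.0])}
        trains.update({i: np.array([200.0 + 0.01 * i]) for i in range(1, 101)})
        sd = SpikeData(trains, {"G": (0, 101)}, 300.0)
        out = spike_filter(sd, window_ms=2.0, min_coactive=10)
        assert 0 not in out.trains
        assert sum(t.size for t in out.trains.values()) == 100

    def test_background_mixture_separated(self):
        rng = np.random.default_rng(6)
        n = 100
        trains = {}
        volley_count = 0
        bg_count = 0
        for i in range(n):
            v = [rng.normal(300.0, 0.5), rng.normal(600.0, 0.5)]
            volley_count += 2
            bg = rng.uniform(0, 1000.0, size=rng.poisson(0.05))
            bg = bg[(np.abs(bg - 300) > 25) & (np.abs(bg - 600) > 25)]
            bg_count += bg.size
            trains[i] = np.unique(np.concatenate([v, bg]))
        sd = SpikeData(trains, {"G": (0, n)}, 1000.0)
        out = spike_filter(sd, window_ms=2.0, min_coactive=10)
        kept = sum(t.size for t in out.trains.values())
        # all volley spikes kept, (essentially) all background removed
        assert kept >= 0.99 * volley_count
        assert kept <= volley_count + 0.01 * max(bg_count, 1) + 1

    def test_idempotent(self):
        trains = {i: np.array([100.0 + 0.02 * i, 400.0 + 0.02 * i])
                  for i in range(50)}
        sd = SpikeData(trains, {"G": (0, 50)}, 500.0)
        once = spike_filter(sd, 2.0, 10)
        twice = spike_filter(once, 2.0, 10)
        assert set(once.trains) == set(twice.trains)
        for k in once.trains:
            assert np.array_equal(once.trains[k], twice.trains[k])


class TestSeparatrix:
    def test_linearly_separable_zero_misclassification(self):
        rng = np.random.default_rng(7)
        sig = rng.uniform(0, 4, 200)
        a = rng.uniform(0, 1.5, 200)
        y = a > 0.7
        keep = np.abs(a - 0.7) > 0.05
        samples = list(zip(sig[keep], a[keep], y[keep]))
        sep = fit_separatrix(samples)
        pred = sep.predict(sig[keep], a[keep]) > 0.5
        assert np.array_equal(pred, y[keep])

    def test_logistic_boundary_recovery_within_10_percent(self):
        rng = np.random.default_rng(8)
        alpha, beta = 0.3, 0.12
        sig = rng.uniform(0, 5, 3000)
        a = rng.uniform(0, 1.6, 3000)
        z = 10.0 * (a - (alpha + beta * sig))
        y = rng.random(3000) < 1.0 / (1.0 + np.exp(-z))
        sep = fit_separatrix(list(zip(sig, a, y)), degree=1)
        s_test = np.array([1.0, 2.0, 3.0, 4.0])
        rec = sep.boundary(s_test)
        true = alpha + beta * s_test
        assert np.all(np.abs(rec - true) / true < 0.10)

    def test_vertical_band_flat_boundary(self):
        rng = np.random.default_rng(9)
        sig = rng.uniform(0, 5, 2000)
        a = rng.uniform(0, 1.0, 2000)
        y = a > 0.5
        sep = fit_separatrix(list(zip(sig, a, y)))
        rec = sep.boundary(np.array([0.5, 2.5, 4.5]))
        assert np.all(np.abs(rec - 0.5) < 0.05)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            fit_separatrix([(1.0, 0.5, True), (2.0, 0.7, True)])

    def test_transition_width_tracks_label_noise(self):
        rng = np.random.default_rng(10)
        sig = rng.uniform(0, 5, 3000)
        a = rng.uniform(0, 1.5, 3000)
        widths = []
        for steep in (20.0, 5.0):
            z = steep * (a - 0.6)
            y = rng.random(3000) < 1.0 / (1.0 + np.exp(-z))
            widths.append(fit_separatrix(list(zip(sig, a, y))).transition_width)
        assert widths[0] < widths[1]   # sharper boundary, narrower band


class TestAIStatistics:
    def test_common_clock_regular_trains(self):
        t = np.arange(100.0, 5000.0, 50.0)
        trains = {i: t.copy() for i in range(20)}
        sd = SpikeData(trains, {"PY": (0, 20)}, 5000.0)
        stats = ai_statistics(sd, "PY")
        assert stats.cv_isi == pytest.approx(0.0, abs=1e-12)
        assert stats.cc == pytest.approx(1.0, abs=1e-9)
        assert stats.survived

    def test_poisson_limits(self):
        sd = poisson_sources(100, 15.0, 12000.0, seed=11)
        sd.populations["PY"] = sd.populations.pop("poisson")
        stats = ai_statistics(sd, "PY")
        assert stats.cv_isi == pytest.approx(1.0, abs=0.1)
        assert abs(stats.cc) < 0.02
        assert stats.mean_rate == pytest.approx(15.0, abs=4 * 15.0 / np.sqrt(
            100 * 15 * 11.5))

    def test_rate_recovery_on_clipped_record(self):
        rng = np.random.default_rng(12)
        r, T = 22.0, 8000.0
        trains = {i: np.sort(rng.uniform(0, T, size=rng.poisson(r * T / 1000)))
                  for i in range(50)}
        trains = {i: t[np.concatenate([[True], np.diff(t) > 1e-6])]
                  for i, t in trains.items()}
        sd = SpikeData(trains, {"PY": (0, 50)}, T)
        stats = ai_statistics(sd, "PY", t_start=0.0)
        se = np.sqrt(r / (50 * T / 1000.0))
        assert stats.mean_rate == pytest.approx(r, abs=4 * se)

    def test_empty_data_not_survived(self):
        sd = SpikeData({}, {"PY": (0, 10)}, 1000.0)
        stats = ai_statistics(sd, "PY")
        assert not stats.survived and stats.mean_rate == 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        trains = {i: np.sort(rng.uniform(0, 4000.0, size=30 + i))
                  for i in range(30)}
        sd = SpikeData(trains, {"PY": (0, 30)}, 4000.0)
        perm = rng.permutation(30)
        sd2 = SpikeData({int(np.where(perm == i)[0][0]): t
                         for i, t in trains.items()}, {"PY": (0, 30)}, 4000.0)
        a = ai_statistics(sd, "PY", t_start=0.0)
        b = ai_statistics(sd2, "PY", t_start=0.0)
        assert a.mean_rate == pytest.approx(b.mean_rate)
        assert a.cv_rates == pytest.approx(b.cv_rates)
        assert a.cv_isi == pytest.approx(b.cv_isi)
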