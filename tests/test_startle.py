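"""Startle-amplitude extraction: baseline, peak, window and aggregation rules."""

import dataclasses

import numpy as np
import pytest

from startlekit.paradigm import build_startle_protocol, noise_burst
from startlekit.startle import (compute_baseline, extract_startle,
                                session_response_table, summarize_session)
from startlekit.synth import PiezoTrace, simulate_piezo

from conftest import replace

RATE = 1000.0


def make_trace(duration_s: float, rate: float = RATE) -> PiezoTrace:
    return PiezoTrace(sampling_rate_hz=rate, samples=np.zeros(int(duration_s * rate)))


class TestComputeBaseline:
    def test_constant_trace(self):
        t = PiezoTrace(RATE, np.full(1000, 0.7))
        b = compute_baseline(t, 1.0)
        assert b.mean == 0.7 and b.sd == 0.0
        assert b.n_samples == 500

    def test_alternating_plus_minus_one_has_unit_sd(self):
        samples = np.tile([1.0, -1.0], 500)
        b = compute_baseline(PiezoTrace(RATE, samples), 1.0)
        assert b.mean == pytest.approx(0.0) and b.sd == pytest.approx(1.0)

    def test_matches_two_pass_oracle_to_1e12(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(2.0, 3.0, 2500)
        b = compute_baseline(PiezoTrace(5000.0, samples), 0.5)
        # independent two-pass computation
        mean = sum(samples) / len(samples)
        sd = (sum((x - mean) ** 2 for x in samples) / len(samples)) ** 0.5
        assert b.mean == pytest.approx(mean, abs=1e-12)
        assert b.sd == pytest.approx(sd, abs=1e-12)

    def test_window_before_trace_start_raises(self):
        with pytest.raises(ValueError, match="0.300"):
            compute_baseline(make_trace(2.0), 0.3)


class TestExtractStartle:
    def test_flat_trace_is_not_a_response(self):
        r = extract_startle(make_trace(2.0), noise_burst(1.0, 90))
        assert r.peak_amplitude == 0.0
        assert not r.is_response
        assert r.scored_amplitude == 0.0

    def test_single_spike_peak_and_latency(self):
        t = make_trace(2.0)
        t.samples[int((1.0 + 0.03) * RATE)] = 5.0
        r = extract_startle(t, noise_burst(1.0, 90))
        assert r.peak_amplitude == 5.0
        assert r.peak_latency_s == pytest.approx(0.03)
        assert r.is_response

    def test_spike_outside_100ms_window_is_missed(self):
        t = make_trace(2.0)
        t.samples[int(1.15 * RATE)] = 5.0
        r = extract_startle(t, noise_burst(1.0, 90))
        assert r.peak_amplitude == 0.0 and not r.is_response

    def test_negative_going_peak_is_rectified(self):
        t = make_trace(2.0)
        t.samples[int(1.02 * RATE)] = -4.0
        r = extract_startle(t, noise_burst(1.0, 90))
        assert r.peak_amplitude == 4.0 and r.is_response

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(0, 1, 2000)
        burst = noise_burst(1.0, 80)
        r0 = extract_startle(PiezoTrace(RATE, samples), burst)
        r1 = extract_startle(PiezoTrace(RATE, samples + 123.4), burst)
        assert r1.peak_amplitude == pytest.approx(r0.peak_amplitude, abs=1e-9)
        assert r1.peak_latency_s == r0.peak_latency_s

    def test_matches_brute_force_scan_on_100_random_traces(self):
        rng = np.random.default_rng(2)
        burst = noise_burst(1.0, 70)
        for _ in range(100):
            samples = rng.normal(0, 1, 1200)
            trace = PiezoTrace(RATE, samples)
            r = extract_startle(trace, burst)
            # exhaustive scan over every sample of the half-open window
            base = samples[500:1000]
            mean = base.sum() / 500
            sd = np.sqrt(((base - mean) ** 2).sum() / 500)
            best_peak, best_i = -1.0, None
            for i in range(1000, 1100):
                dev = abs(samples[i] - mean)
                if dev > best_peak:
                    best_peak, best_i = dev, i
            assert r.peak_amplitude == best_peak
            assert r.peak_latency_s == (best_i - 1000) / RATE
            assert r.is_response == (best_peak > 2 * sd)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError, match="trace ends"):
            extract_startle(make_trace(1.05), noise_burst(1.0, 90))


class TestSummarizeSession:
    def test_means_over_scored_amplitudes(self, startle_protocol):
        trace = make_trace(1115.0, rate=1000.0)
        bursts_90 = [e for e in startle_protocol.events if e.intensity_db == 90]
        for amp, burst in zip([1, 2, 3, 4, 5], bursts_90):
            trace.samples[int((burst.onset_s + 0.02) * 1000)] = float(amp)
        summaries = {s.intensity_db: s for s in summarize_session(trace, startle_protocol)}
        assert summaries[90.0].mean_amplitude == pytest.approx(3.0)
        assert summaries[90.0].n_trials == 5

    def test_all_nonresponses_score_zero(self, startle_protocol):
        summaries = summarize_session(make_trace(1115.0), startle_protocol)
        assert [s.mean_amplitude for s in summaries] == [0.0] * 4

    def test_noiseless_closed_loop_recovers_gain_exactly(self, startle_protocol, quiet_sim):
        cfg = replace(quiet_sim, startle_gain={70: 10.0, 80: 20.0, 90: 40.0, 100: 80.0})
        trace, _ = simulate_piezo(startle_protocol, cfg, "wt")
        for s in summarize_session(trace, startle_protocol):
            assert s.mean_amplitude == pytest.approx(cfg.startle_gain[int(s.intensity_db)],
                                                     abs=1e-9)

    def test_drop_policy_excludes_subthreshold_trials(self, startle_protocol):
        rng = np.random.default_rng(3)
        trace = PiezoTrace(1000.0, rng.normal(0, 1, int(1115 * 1000)))
        # large spike on one 70 dB burst only; others are noise (mostly sub-threshold)
        burst = next(e for e in startle_protocol.events if e.intensity_db == 70)
        trace.samples[int((burst.onset_s + 0.05) * 1000)] = 50.0
        drop = {s.intensity_db: s for s in
                summarize_session(trace, startle_protocol, nonresponse="drop")}
        zero = {s.intensity_db: s for s in
                summarize_session(trace, startle_protocol, nonresponse="zero")}
        assert drop[70.0].n_trials <= 5
        assert drop[70.0].mean_amplitude >= zero[70.0].mean_amplitude

    def test_intensity_monotonic_recovery_with_default_snr(self, startle_protocol):
        # gains increase with dB, so per-intensity means should too (high SNR)
        from startlekit.presets import preset_config
        sim = preset_config("spasmodic")
        ok = 0
        for seed in range(20):
            trace, _ = simulate_piezo(startle_protocol, replace(sim, seed=seed), "wt")
            means = [s.mean_amplitude for s in summarize_session(trace, startle_protocol)]
            ok += all(a <= b for a, b in zip(means, means[1:]))
        assert ok >= 19  # >= 95% of simulated animals


def test_response_table_has_one_row_per_burst(startle_protocol, quiet_sim):
    trace, _ = simulate_piezo(startle_protocol, quiet_sim, "wt")
    table = session_response_table(trace, startle_protocol)
    assert len(table) == 20
    assert list(table.burst_index) == list(range(20))
    assert set(table.columns) >= {"intensity_db", "peak_amplitude", "latency_s",
                                  "is_response", "baseline_mean", "baseline_sd"}
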