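"""Passive properties, spike metrics, F-I curves, SFA and mini detection."""

import numpy as np
import pytest

from ephyskit import intracellular as ic
from ephyskit import synth
from ephyskit.intracellular import (DegenerateThresholdError,
                                    EstimationError,
                                    InsufficientSpikesError, TraceSweep,
                                    detect_minis, detect_spikes, fi_curve,
                                    mini_stats, passive_properties,
                                    sfa_index)


class TestPassiveProperties:
    def test_ideal_rc_recovers_rin_and_cm(self):
        # -5 mV step, R = 200 MOhm -> steady-state -25 pA; tau = 13 ms
        sweep = synth.gen_rc_step_sweep(r_mohm=200.0, cm_pf=65.0)
        p = passive_properties(sweep)
        assert p.input_resistance_mohm == pytest.approx(200.0, rel=1e-3)
        assert p.time_constant_ms == pytest.approx(13.0, rel=1e-2)
        assert p.capacitance_pf == pytest.approx(65.0, rel=1e-2)

    def test_noisy_rc_recovers_rin_within_5_percent(self):
        errs = []
        for seed in range(5):
            sweep = synth.gen_rc_step_sweep(r_mohm=200.0, cm_pf=65.0,
                                            noise_sd_pa=1.0, seed=seed)
            errs.append(abs(passive_properties(sweep).input_resistance_mohm
                            - 200.0) / 200.0)
        assert max(errs) < 0.05

    def test_flat_sweep_raises_estimation_error(self):
        sweep = TraceSweep(np.zeros(2000), 20000.0, units="pA",
                           annotations={"step_mv": -5.0, "onset_s": 0.02,
                                        "offset_s": 0.08})
        with pytest.raises(EstimationError):
            passive_properties(sweep)


def _triangular_spike(fs=20000.0):
    """Linear rise -60 -> +20 mV over 1 ms, fall to -60 over 2 ms."""
    n_rise, n_fall = int(1e-3 * fs), int(2e-3 * fs)
    v = np.concatenate([
        np.full(int(5e-3 * fs), -60.0),
        np.linspace(-60.0, 20.0, n_rise, endpoint=False),
        np.linspace(20.0, -60.0, n_fall, endpoint=False),
        np.full(int(5e-3 * fs), -60.0)])
    return TraceSweep(v, fs, units="mV")


class TestSpikes:
    def test_subthreshold_sweep_has_no_spikes(self):
        sweep = TraceSweep(np.full(1000, -65.0), 20000.0, units="mV")
        assert detect_spikes(sweep).count == 0

    def test_triangular_spike_half_width_closed_form(self):
        # threshold = -60 (rise slope 80 V/s exceeds criterion throughout);
        # half level = -20 mV; crossings at 0.5 ms before and 1 ms after
        # the peak -> width 1.5 ms
        sweep = _triangular_spike()
        m = detect_spikes(sweep)
        assert m.count == 1
        assert m.thresholds_mv[0] == pytest.approx(-60.0, abs=1.0)
        assert m.half_widths_ms[0] == pytest.approx(1.5, abs=1.0 / 20.0)

    def test_detected_times_match_simulator_truth(self, if_session):
        for sweep, truth in zip(if_session.sweeps, if_session.spike_times):
            m = detect_spikes(sweep)
            assert m.count == truth.size
            if truth.size:
                assert np.max(np.abs(m.times_s - truth)) <= 1e-3


class TestFICurve:
    def test_all_subthreshold_counts_are_zero(self):
        ses = synth.gen_current_step_session(steps_pa=(-100, -50, 0, 50),
                                             seed=0)
        _, counts = fi_curve(ses)
        assert np.all(counts == 0)

    def test_noiseless_fi_curve_non_decreasing(self, if_session):
        steps, counts = fi_curve(if_session)
        assert np.all(np.diff(counts) >= 0)

    def test_first_spiking_step_matches_rheobase_closed_form(self, if_session):
        steps, counts = fi_curve(if_session)
        rheo = if_session.params.rheobase_pa
        # asymptotic drive equals threshold exactly at rheobase, so the
        # first spiking step is the smallest ladder step strictly above it
        predicted = steps[steps > rheo].min()
        first = steps[np.flatnonzero(counts > 0)[0]]
        assert first == predicted


class TestSFA:
    def test_regular_train_is_unity(self):
        assert sfa_index(np.arange(8) * 0.1) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        isis = np.array([50, 60, 70, 80, 90, 100]) / 1000.0
        times = np.concatenate([[0.0], np.cumsum(isis)])
        assert sfa_index(times) == pytest.approx(70.0 / 90.0, abs=1e-12)

    def test_adapting_neuron_has_sfa_below_one(self, if_session):
        step, times = ic.select_sfa_step(if_session)
        assert sfa_index(times) < 1.0

    def test_too_few_spikes_rejected(self):
        with pytest.raises(InsufficientSpikesError):
            sfa_index([0.0, 0.1, 0.2])


class TestDetectMinis:
    def test_noiseless_planted_events_recovered_exactly(self):
        truth = synth.MiniGroundTruth(np.arange(10) * 1.0 + 0.5,
                                      np.full(10, 20.0))
        sweep, _ = synth.gen_mini_sweep(truth, 11.0, 10000.0)
        ev = detect_minis(sweep, "inward")
        assert ev.times_s.size == 10
        np.testing.assert_allclose(ev.amplitudes_pa, 20.0, rtol=0.01)

    def test_false_positive_count_matches_crossing_oracle(self):
        # pure noise: detector events = clusters of above-threshold samples
        # in the smoothed rectified trace; recompute that count directly
        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 4.0, 200000)
        sweep = TraceSweep(x, 10000.0, units="pA")
        ev = detect_minis(sweep, "inward", min_interval_ms=5.0)
        r = -(x - np.median(x))
        sigma = 1.4826 * np.median(np.abs(r - np.median(r)))
        det = np.convolve(r, np.ones(10) / 10, mode="same")
        above = det > 3.0 * sigma
        # count merged clusters with the same 5-ms gap rule
        idx = np.flatnonzero(above)
        n_oracle = 1 + int(np.sum(np.diff(idx) >= 50)) if idx.size else 0
        assert ev.times_s.size == n_oracle

    def test_detection_translates_and_scales(self):
        truth = synth.MiniGroundTruth(np.array([0.2, 0.6]),
                                      np.array([15.0, 25.0]),
                                      noise_sd_pa=2.0)
        sweep, _ = synth.gen_mini_sweep(truth, 1.0, 10000.0, seed=3)
        ev1 = detect_minis(sweep, "inward")
        scaled = TraceSweep(sweep.samples * 3.0, 10000.0, units="pA")
        ev2 = detect_minis(scaled, "inward")
        np.testing.assert_allclose(ev2.times_s, ev1.times_s)
        np.testing.assert_allclose(ev2.amplitudes_pa,
                                   3.0 * ev1.amplitudes_pa, rtol=1e-9)

    def test_snr5_benchmark_recall_and_precision(self):
        truth = synth.gen_mini_truth(3.0, 30.0, seed=13)
        truth = synth.MiniGroundTruth(truth.event_times_s,
                                      np.full(truth.event_times_s.size, 20.0),
                                      noise_sd_pa=4.0)
        sweep, _ = synth.gen_mini_sweep(truth, 30.0, 10000.0, seed=14)
        ev = detect_minis(sweep, "inward")
        recall = np.mean([np.any(np.abs(ev.times_s - t) < 0.005)
                          for t in truth.event_times_s])
        precision = np.mean([np.any(np.abs(truth.event_times_s - t) < 0.005)
                             for t in ev.times_s])
        assert recall >= 0.9
        assert precision >= 0.9

    def test_degenerate_threshold_raises(self):
        sweep = TraceSweep(np.zeros(1000), 10000.0, units="pA")
        with pytest.raises(DegenerateThresholdError):
            detect_minis(sweep, "inward", threshold_sd=0.0)


class TestMiniStats:
    def test_frequency_and_histogram_bookkeeping(self):
        ev = ic.MiniEventTable(np.linspace(0, 99, 300),
                               np.array([10.2, 10.7, 11.3] * 100),
                               "inward", 100.0, 5.0)
        s = mini_stats(ev)
        assert s.frequency_hz == pytest.approx(3.0)
        assert s.histogram[10] == 200  # [10, 11)
        assert s.histogram[11] == 100  # [11, 12)
        assert s.histogram.sum() == 300

    def test_ecdf_steps_by_one_over_n_and_ends_at_one(self):
        ev = ic.MiniEventTable(np.arange(5) * 1.0,
                               np.array([3.0, 1.0, 4.0, 1.5, 9.0]),
                               "inward", 10.0, 0.5)
        s = mini_stats(ev)
        assert np.allclose(np.diff(s.ecdf_y), 0.2)
        assert s.ecdf_y[-1] == 1.0
        assert np.all(np.diff(s.ecdf_x) >= 0)

    def test_histogram_matches_brute_force_recount(self):
        rng = np.random.default_rng(15)
        amps = rng.gamma(4.0, 5.0, 200)
        ev = ic.MiniEventTable(np.sort(rng.uniform(0, 50, 200)), amps,
                               "inward", 50.0, 1.0)
        s = mini_stats(ev)
        for i in range(len(s.histogram)):
            brute = int(np.sum((amps >= i) & (amps < i + 1)))
            assert s.histogram[i] == brute

    def test_empty_table_gives_zero_frequency(self):
        ev = ic.MiniEventTable(np.array([]), np.array([]), "inward",
                               10.0, 1.0)
        s = mini_stats(ev)
        assert s.frequency_hz == 0.0
        assert s.histogram.size == 0
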