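"""Spike/barrage/onset/rise-time detection against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from astrobarrage import (
    AstrocyteEvent,
    BarrageEvent,
    GeneratorSpec,
    all_points_histogram,
    analyze_recording,
    build_timeline,
    count_spikes_to_induction,
    detect_barrage,
    detect_onset,
    detect_spikes,
    make_protocol,
    measure_astrocyte_event,
    rise_time_20_80,
)

from conftest import analyzed_cohort


def make_spike_trace(spike_times, fs, duration, resting=-65.0):
    trace = np.full(int(duration * fs), resting)
    for t in spike_times:
        i = int(round(t * fs))
        trace[i : i + 2] = 30.0
    return trace


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        trace = np.full(1000, -65.0)
        assert detect_spikes(trace, 1000.0).size == 0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_spikes(np.empty(0), 1000.0)

    def test_inserted_waveforms_recovered(self):
        fs = 10_000.0
        inserted = np.sort(np.random.default_rng(0).uniform(0.1, 3.9, 40))
        inserted = inserted[np.concatenate([[True], np.diff(inserted) > 0.005])]
        trace = make_spike_trace(inserted, fs, 4.0)
        detected = detect_spikes(trace, fs)
        assert detected.size == inserted.size
        assert np.all(np.abs(detected - inserted) <= 1.5 / fs)

    def test_refractory_merges_close_crossings(self):
        fs = 10_000.0
        trace = make_spike_trace([0.100, 0.101], fs, 1.0)
        assert detect_spikes(trace, fs, refractory_s=0.002).size == 1


class TestDetectBarrage:
    def test_six_hertz_after_step_end_detected_at_step_end(self):
        protocol = make_protocol(n_sweeps=5, sampling_rate=1000.0, t0=0.0)
        step_end = 4 * 3.0 + 1.0  # end of the last step
        spikes = step_end + np.arange(9) / 6.0  # 6 Hz for 1.5 s
        event = detect_barrage(spikes, protocol)
        assert event is not None
        assert event.onset == pytest.approx(step_end)

    def test_silence_after_steps_gives_none(self):
        protocol = make_protocol(n_sweeps=5, t0=0.0)
        # only evoked spikes inside steps
        spikes = np.concatenate(
            [3.0 * k + np.linspace(0.1, 0.9, 20) for k in range(5)]
        )
        assert detect_barrage(spikes, protocol) is None

    def test_exactly_four_hertz_is_not_barrage(self):
        """Strict '>' criterion: 4.0 Hz never qualifies; confirmed against
        an exhaustive window-rate oracle."""
        protocol = make_protocol(n_sweeps=3, t0=0.0)
        step_end = 2 * 3.0 + 1.0
        spikes = step_end + 0.125 + 0.25 * np.arange(40)  # exactly 4 Hz
        assert detect_barrage(spikes, protocol) is None
        # oracle: enumerate every candidate 1-s window at 0.1-s stride
        horizon = spikes[-1] + 1.0
        t = step_end
        while t + 1.0 <= horizon:
            n = np.sum((spikes >= t) & (spikes <= t + 1.0))
            assert not n / 1.0 > 4.0
            t += 0.1

    def test_windows_never_overlap_steps(self):
        """Evoked spikes at 40 Hz inside steps must not trigger detection."""
        protocol = make_protocol(n_sweeps=10, t0=0.0)
        rng = np.random.default_rng(1)
        spikes = np.sort(
            np.concatenate(
                [rng.uniform(3.0 * k, 3.0 * k + 1.0, 40) for k in range(10)]
            )
        )
        assert detect_barrage(spikes, protocol) is None

    def test_duration_and_counts_of_dense_train(self):
        protocol = make_protocol(n_sweeps=4, t0=0.0)
        step_end = 3 * 3.0 + 1.0
        spikes = step_end + np.arange(0, 20.0, 0.05)  # 20 Hz for 20 s
        event = detect_barrage(spikes, protocol)
        assert event.onset == pytest.approx(step_end)
        assert event.duration == pytest.approx(20.0, abs=1.1)
        assert event.n_barrage_spikes >= 395


class TestCountSpikesToInduction:
    def test_fifteen_full_steps_of_forty(self):
        protocol = make_protocol(n_sweeps=20, t0=0.0)
        spikes = np.concatenate(
            [3.0 * k + (np.arange(1, 41)) / 41.0 for k in range(20)]
        )
        onset = 15 * 3.0 - 2.0  # end of the 15th step
        assert count_spikes_to_induction(spikes, protocol, onset) == 600

    def test_onset_before_first_step_counts_zero(self):
        protocol = make_protocol(n_sweeps=5, t0=10.0)
        spikes = 10.0 + np.linspace(0.1, 0.9, 40)
        assert count_spikes_to_induction(spikes, protocol, 5.0) == 0

    def test_mid_step_onset_excludes_later_spikes(self):
        """Enumeration oracle: spikes in the inducing step after the onset
        are excluded."""
        protocol = make_protocol(n_sweeps=3, t0=0.0)
        rng = np.random.default_rng(2)
        spikes = np.sort(
            np.concatenate([rng.uniform(3.0 * k, 3.0 * k + 1.0, 40) for k in range(3)])
        )
        onset = 6.5  # middle of the third step
        expected = sum(
            1
            for s in spikes
            if s < onset
            and any(3.0 * k <= s < 3.0 * k + 1.0 for k in range(3))
        )
        assert count_spikes_to_induction(spikes, protocol, onset) == expected

    def test_cohort_mean_recovers_generator_target(self, strong_cohort_small):
        counts = [
            a.barrage.spikes_to_induction
            for _, a in strong_cohort_small
            if a.barrage is not None
        ]
        truth = [
            b.truth.realized_spikes_to_induction
            for b, a in strong_cohort_small
            if a.barrage is not None
        ]
        # near-exact: spikes within half a sample of the step-end boundary
        # may quantize onto the barrage onset and drop out of the count
        diffs = np.abs(np.array(counts) - np.array(truth))
        assert diffs.max() <= 3
        assert abs(np.mean(counts) - np.mean(truth)) <= 0.01 * np.mean(truth)


class TestDetectOnset:
    def test_constant_trace_has_no_onset(self):
        trace = np.full(2000, -80.0)
        assert detect_onset(trace, 100.0, (0.0, 10.0)) is None

    def test_step_onset_matches_exhaustive_scan_oracle(self):
        fs = 100.0
        rng = np.random.default_rng(3)
        trace = rng.normal(-80.0, 0.5, int(100 * fs))
        onset_true = 50.0
        trace[int(onset_true * fs) :] += 10.0
        onset = detect_onset(trace, fs, (0.0, 30.0), k_sd=3.0, sustain_s=0.5)
        assert onset == pytest.approx(onset_true, abs=0.1)
        # exhaustive scan oracle
        mu = trace[: int(30 * fs)].mean()
        sd = trace[: int(30 * fs)].std()
        need = int(0.5 * fs)
        above = trace > mu + 3 * sd
        expected = None
        for i in range(int(30 * fs), trace.size - need + 1):
            if above[i : i + need].all():
                expected = i / fs
                break
        assert onset == pytest.approx(expected)

    def test_zero_variance_baseline_detects_first_deviation(self):
        fs = 100.0
        trace = np.full(int(40 * fs), -80.0)
        trace[int(20 * fs) :] += 1e-6
        onset = detect_onset(trace, fs, (0.0, 10.0))
        assert onset == pytest.approx(20.0)

    def test_noiseless_astro_onsets_always_precede_barrage(self):
        cohort = analyzed_cohort(
            8, seed=31, sampling_rate=500.0,
            vm_noise_sd=0.0, astro_event_probability=1.0,
        )
        seen = 0
        for bundle, analysis in cohort:
            if analysis.barrage is None:
                continue
            assert analysis.astro is not None
            assert analysis.astro.onset < analysis.barrage.onset
            seen += 1
        assert seen >= 6


class TestRiseTime:
    def test_linear_ramp_gives_sixty_percent_of_duration(self):
        fs = 1000.0
        t = np.arange(int(3 * fs)) / fs
        trace = np.zeros(t.size)
        ramp = (t >= 1.0) & (t < 2.0)
        trace[ramp] = 10.0 * (t[ramp] - 1.0)
        trace[t >= 2.0] = 10.0
        rt = rise_time_20_80(trace, fs, onset=1.0, baseline_mean=0.0)
        assert rt == pytest.approx(0.6, abs=2 / fs)

    def test_generator_sigmoid_recovers_calibrated_rise(self):
        """A logistic rise parameterized for a 1.3-s 20-80% time yields 1.3 s."""
        fs = 1000.0
        s = 1.3 / (2 * np.log(4.0))
        t = np.arange(int(40 * fs)) / fs
        trace = 10.3 / (1.0 + np.exp(-(t - 20.0) / s))
        rt = rise_time_20_80(trace, fs, onset=10.0, baseline_mean=0.0)
        assert rt == pytest.approx(1.3, abs=2 / fs)

    def test_monotone_waveform_matches_dense_resampling_oracle(self):
        fs = 200.0
        t = np.arange(int(4 * fs)) / fs
        waveform = 5.0 * np.clip(np.sin(np.clip(t - 1.0, 0, np.pi / 2)) ** 3, 0, 1)
        rt = rise_time_20_80(waveform, fs, onset=1.0, baseline_mean=0.0)
        # dense numerical oracle at 100x resolution
        td = np.arange(int(4 * fs * 100)) / (fs * 100)
        dense = 5.0 * np.clip(np.sin(np.clip(td - 1.0, 0, np.pi / 2)) ** 3, 0, 1)
        peak = dense.max()
        t20 = td[np.argmax(dense >= 0.2 * peak)]
        t80 = td[np.argmax(dense >= 0.8 * peak)]
        assert rt == pytest.approx(t80 - t20, abs=1.5 / fs)


class TestAllPointsHistogram:
    def test_constant_trace_fills_single_bin(self):
        edges, counts = all_points_histogram(np.full(500, -80.0), 1.0)
        assert counts.sum() == 500
        assert (counts > 0).sum() == 1

    def test_bimodal_trace_splits_evenly(self):
        trace = np.concatenate([np.full(300, -80.0), np.full(300, -70.0)])
        edges, counts = all_points_histogram(trace, 1.0)
        nz = counts[counts > 0]
        assert list(nz) == [300, 300]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=10_000))
    def test_sample_count_conserved(self, seed):
        trace = np.random.default_rng(seed).normal(-75.0, 3.0, 400)
        edges, counts = all_points_histogram(trace, 0.5)
        assert counts.sum() == 400
        # direct counting oracle, bin by bin
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            is_last = hi == edges[-1]
            direct = np.sum(
                (trace >= lo) & ((trace <= hi) if is_last else (trace < hi))
            )
            assert direct == c


class TestTimeline:
    def test_lead_zero_when_signal_starts_with_barrage(self):
        astro = AstrocyteEvent(onset=60.0, peak_amplitude=10.0)
        barrage = BarrageEvent(onset=60.0, end=90.0)
        tl = build_timeline(30.0, astro, barrage)
        assert tl.lead == 0.0

    def test_population_lead_arithmetic(self):
        astro = AstrocyteEvent(onset=60.0, peak_amplitude=10.0)
        barrage = BarrageEvent(onset=89.5, end=120.0)
        tl = build_timeline(30.0, astro, barrage)
        assert tl.lead == pytest.approx(29.5)

    def test_overhang_arithmetic(self):
        barrage = BarrageEvent(onset=90.0, end=120.0)
        tl = build_timeline(30.0, None, barrage, signal_end=150.0)
        assert tl.overhang == pytest.approx(150.0 - 120.0)

    def test_missing_barrage_leaves_lead_undefined(self):
        astro = AstrocyteEvent(onset=60.0, peak_amplitude=10.0)
        tl = build_timeline(30.0, astro, None)
        assert tl.lead is None and tl.overhang is None

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            build_timeline(30.0, None, None)


class TestNoiselessRecovery:
    def test_all_event_parameters_recovered(self, noiseless_strong_bundle):
        """On a noiseless bundle, detection reproduces the ground truth up to
        sampling/windowing quantization."""
        bundle = noiseless_strong_bundle
        truth = bundle.truth
        analysis = analyze_recording(bundle)
        fs = bundle.sampling_rate
        assert analysis.barrage is not None
        assert analysis.barrage.onset == pytest.approx(truth.barrage_onset, abs=0.2)
        assert analysis.barrage.duration == pytest.approx(
            truth.barrage_duration, abs=1.1
        )
        assert analysis.astro is not None
        assert analysis.astro.onset == pytest.approx(truth.astro_onset, abs=2 / fs)
        assert analysis.astro.peak_amplitude == pytest.approx(
            truth.astro_peak_mv, abs=0.05
        )
        assert analysis.astro.rise_time_20_80 == pytest.approx(
            truth.astro_rise_time, abs=0.1
        )
        assert analysis.timeline.lead == pytest.approx(truth.depol_lead, abs=0.3)

    def test_qc_flag_for_slow_induction(self):
        spec = GeneratorSpec(spikes_to_induction_mean=2400.0, spikes_to_induction_sd=0.0)
        protocol = make_protocol(n_sweeps=70, sampling_rate=500.0)
        from astrobarrage import generate_recording

        bundle = generate_recording(spec, protocol, seed=12)
        analysis = analyze_recording(bundle)
        assert analysis.barrage is not None
        assert analysis.qc_flag
        assert "evoked spikes" in analysis.qc_reason


class TestMeasureAstrocyteEvent:
    def test_no_event_in_flat_noise(self):
        rng = np.random.default_rng(8)
        trace = rng.normal(-80.0, 0.3, 20_000)
        assert measure_astrocyte_event(trace, 200.0, (0.0, 30.0)) is None
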