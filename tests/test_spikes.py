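"""Spike detector: baseline robustness, threshold criteria, invariances."""

import numpy as np
import pytest

from helpers import sensitivity_precision
from swdkit.eeg_io import EEGRecording, EventTable
from swdkit.simulate import EEGSimParams, generate_eeg, spike_template
from swdkit.spikes import (
    DetectionParams,
    SpikeEvent,
    detect_spikes,
    estimate_baseline,
    spike_frequency,
)


def _noise_recording(seed=0, duration=60.0, sigma=10.0, fs=1000.0):
    rng = np.random.default_rng(seed)
    return EEGRecording(rng.normal(0, sigma, (1, int(duration * fs))), fs)


class TestBaseline:
    def test_gaussian_noise_baseline_matches_sigma(self):
        rec = _noise_recording(sigma=10.0)
        prof = estimate_baseline(rec)
        assert np.all(np.abs(prof.amplitude - 10.0) / 10.0 < 0.10)

    def test_huge_spike_barely_moves_baseline(self):
        rec = _noise_recording(seed=1, sigma=10.0)
        prof0 = estimate_baseline(rec)
        spiked = rec.samples.copy()
        spiked[0, 5000:5030] += 500.0
        prof1 = estimate_baseline(EEGRecording(spiked, rec.sampling_rate))
        assert np.all(np.abs(prof1.amplitude - prof0.amplitude) / prof0.amplitude < 0.02)

    def test_constant_trace_floors_with_warning(self):
        rec = EEGRecording(np.zeros((1, 30_000)), 1000.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = estimate_baseline(rec)
        assert np.all(prof.amplitude == 1e-6)

    def test_fully_artifact_covered_trace_errors(self):
        rec = _noise_recording(duration=10.0)
        artifacts = EventTable.from_events([(0.0, 10.0, "artifact", "ch1")])
        with pytest.raises(ValueError, match="no baseline estimable"):
            estimate_baseline(rec, artifacts=artifacts)

    def test_artifact_window_inherits_neighbor(self):
        rec = _noise_recording(duration=30.0)
        artifacts = EventTable.from_events([(10.0, 20.0, "artifact", "ch1")])
        prof = estimate_baseline(rec, artifacts=artifacts)
        assert len(prof.amplitude) == 3
        assert np.all(prof.amplitude > 0)


class TestDetectSpikes:
    def test_lone_spike_on_flat_trace_detected(self):
        x = np.zeros(30_000)
        tpl = spike_template(1000.0, 100.0)
        x[15_000 : 15_000 + len(tpl)] += tpl
        with pytest.warns(UserWarning, match="zero-variance"):
            events = detect_spikes(EEGRecording(x[None, :], 1000.0))
        assert len(events) == 1
        assert abs(events[0].time - 15.0) < 0.02

    def test_three_fold_deflection_rejected(self):
        rec, _ = generate_eeg(
            EEGSimParams(duration=60, seed=5, spike_rate=0, swd_rate=0, artifact_rate=0)
        )
        x = rec.samples[0].copy()
        prof = estimate_baseline(rec)
        tpl = spike_template(1000.0, 3.0 * float(prof.amplitude.mean()))
        x[30_000 : 30_000 + len(tpl)] += tpl
        events = detect_spikes(EEGRecording(x[None, :], 1000.0))
        assert not any(abs(e.time - 30.0) < 0.05 for e in events)

    def test_six_fold_deflection_detected(self):
        rec, _ = generate_eeg(
            EEGSimParams(duration=60, seed=5, spike_rate=0, swd_rate=0, artifact_rate=0)
        )
        x = rec.samples[0].copy()
        prof = estimate_baseline(rec)
        tpl = spike_template(1000.0, 6.0 * float(prof.amplitude.mean()))
        x[30_000 : 30_000 + len(tpl)] += tpl
        events = detect_spikes(EEGRecording(x[None, :], 1000.0))
        assert any(abs(e.time - 30.0) < 0.05 for e in events)

    def test_retained_events_satisfy_both_criteria(self):
        rec, truth = generate_eeg(EEGSimParams(duration=300, seed=6, spike_rate=240))
        params = DetectionParams()
        events = detect_spikes(rec, params, truth.artifact_table())
        assert events, "expected detections"
        for e in events:
            assert e.amplitude_ratio >= params.amplitude_ratio_threshold
            assert e.sharpness >= params.sharpness_threshold

    def test_dc_offset_invariance(self):
        rec, truth = generate_eeg(EEGSimParams(duration=120, seed=7, spike_rate=240))
        events0 = detect_spikes(rec, artifacts=truth.artifact_table())
        shifted = EEGRecording(rec.samples + 500.0, rec.sampling_rate, rec.channel_labels)
        events1 = detect_spikes(shifted, artifacts=truth.artifact_table())
        assert [e.time for e in events0] == [e.time for e in events1]
        np.testing.assert_allclose(
            [e.amplitude for e in events0], [e.amplitude for e in events1], rtol=1e-9
        )

    def test_positive_scaling_preserves_ratio_and_scales_amplitude(self):
        """Scaling by c scales amplitudes by c and leaves ratios unchanged.

        The amplitude gate is scale-invariant but the absolute sharpness
        gate is not, so scaling up may *add* events; every original event
        must persist with scaled amplitude and identical ratio.
        """
        rec, truth = generate_eeg(EEGSimParams(duration=120, seed=8, spike_rate=240))
        events0 = detect_spikes(rec, artifacts=truth.artifact_table())
        c = 3.0
        scaled = EEGRecording(rec.samples * c, rec.sampling_rate, rec.channel_labels)
        events1 = {e.time: e for e in detect_spikes(scaled, artifacts=truth.artifact_table())}
        assert events0, "expected detections"
        for e in events0:
            assert e.time in events1
            assert events1[e.time].amplitude == pytest.approx(c * e.amplitude, rel=1e-9)
            assert events1[e.time].amplitude_ratio == pytest.approx(e.amplitude_ratio, rel=1e-9)

    def test_candidate_count_conservation(self):
        rec, truth = generate_eeg(EEGSimParams(duration=300, seed=9, artifact_rate=60))
        events, counts = detect_spikes(
            rec, artifacts=truth.artifact_table(), return_counts=True
        )
        assert (
            counts["retained"] + counts["artifact_excluded"] + counts["below_threshold"]
            == counts["candidates"]
        )
        assert counts["retained"] == sum(1 for e in events if not e.excluded_artifact)

    def test_artifact_spikes_flagged_and_excluded(self):
        rec, truth = generate_eeg(
            EEGSimParams(duration=600, seed=10, spike_rate=60, artifact_rate=60)
        )
        events = detect_spikes(rec, artifacts=truth.artifact_table())
        flagged = [e for e in events if e.excluded_artifact]
        iv = truth.artifact_table().intervals()
        for e in flagged:
            assert any(s <= e.time < t for s, t in iv)

    def test_low_sampling_rate_rejected(self):
        rec = EEGRecording(np.zeros((1, 1000)), 100.0)
        with pytest.raises(ValueError, match="sampling rate"):
            detect_spikes(rec)

    def test_detector_validity_on_synthetic_recording(self):
        rec, truth = generate_eeg(EEGSimParams(duration=600, seed=12))
        events = detect_spikes(rec, artifacts=truth.artifact_table())
        det = [e.time for e in events if not e.excluded_artifact]
        sens, prec = sensitivity_precision(det, truth.all_sharp_transient_times)
        assert sens >= 0.95
        assert prec >= 0.95


class TestSpikeFrequency:
    @staticmethod
    def _spike(t, member=False, artifact=False):
        return SpikeEvent(t, "ch1", 100.0, 6.0, 10.0, member, artifact)

    def test_swd_members_excluded_from_rate(self):
        spikes = [self._spike(i * 10.0) for i in range(120)]
        spikes += [self._spike(2000 + i * 0.08, member=True) for i in range(20)]
        assert spike_frequency(spikes, analyzed_duration=12 * 3600.0) == pytest.approx(10.0)

    def test_zero_spikes(self):
        assert spike_frequency([], analyzed_duration=3600.0) == 0.0

    def test_all_members_gives_zero(self):
        spikes = [self._spike(i * 0.08, member=True) for i in range(40)]
        assert spike_frequency(spikes, analyzed_duration=3600.0) == 0.0

    def test_artifact_spikes_not_counted(self):
        spikes = [self._spike(1.0), self._spike(2.0, artifact=True)]
        assert spike_frequency(spikes, analyzed_duration=3600.0) == pytest.approx(1.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            spike_frequency([], analyzed_duration=0.0)
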