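import numpy as np
import pytest

import ripplemap as rm
from ripplemap.events import (
    EpochEvent,
    auto_baseline_epochs,
    detect_hfo,
    detect_swd,
    prevalence_table,
    segment_burst_suppression,
)
from ripplemap.filters import band_by_name
from ripplemap.synth import SynthConfig, lesion_config, make_recording, packet_amplitude

HFR = band_by_name("HFR")


def _mask(epochs, duration, fs=100.0):
    m = np.zeros(int(duration * fs), dtype=bool)
    for s, e in epochs:
        m[int(s * fs): int(e * fs)] = True
    return m


class TestBurstSuppression:
    def test_recovers_ground_truth_epochs(self, lesion_recording):
        cfg, rec, gt = lesion_recording
        events = segment_burst_suppression(rec)
        bursts = [(e.start, e.end) for e in events if e.kind == "burst"]
        mg = _mask(gt.burst_epochs, cfg.duration)
        md = _mask(bursts, cfg.duration)
        jaccard = (mg & md).sum() / (mg | md).sum()
        assert jaccard >= 0.90

    def test_epochs_alternate_and_cover(self, lesion_recording):
        _, rec, _ = lesion_recording
        events = segment_burst_suppression(rec)
        assert events[0].start == 0.0
        assert events[-1].end == pytest.approx(rec.duration)
        for a, b in zip(events, events[1:]):
            assert a.end == pytest.approx(b.start)
            assert a.kind != b.kind

    def test_constant_sinusoid_is_one_burst(self):
        fs = 2000.0
        t = np.arange(int(10 * fs)) / fs
        ev = segment_burst_suppression(100 * np.sin(2 * np.pi * 10 * t), fs=fs)
        assert len(ev) == 1 and ev[0].kind == "burst"

    def test_noise_floor_is_suppression(self, rng):
        fs = 2000.0
        ev = segment_burst_suppression(rng.normal(0, 2, int(10 * fs)), fs=fs)
        assert all(e.kind == "suppression" for e in ev)

    def test_flat_signal_warns(self):
        with pytest.warns(UserWarning, match="flat"):
            ev = segment_burst_suppression(np.zeros(20_000), fs=2000.0)
        assert len(ev) == 1 and ev[0].kind == "suppression"

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            segment_burst_suppression(np.zeros(100), fs=100.0)


class TestSWD:
    def test_clean_train_recovered_with_tight_boundaries(self):
        cfg = SynthConfig(seed=5, duration=15.0, swd_freq=11.0, swd_dur=2.0,
                          n_swd=1, noise_std=2.0, burst_lfp_std=5.0)
        rec, gt = make_recording(cfg)
        ev = detect_swd(rec.samples[0], rec.fs)
        assert len(ev) == 1
        s, e = gt.swd_epochs[0]
        assert ev[0].start == pytest.approx(s, abs=0.1)
        assert ev[0].end == pytest.approx(e, abs=0.1)

    @pytest.mark.parametrize("seed", [3, 8, 10, 15, 18])
    def test_noisy_recordings_detected(self, seed):
        cfg = lesion_config(seed=seed, duration=15.0)
        rec, gt = make_recording(cfg)
        ev = detect_swd(rec.samples[0], rec.fs)
        assert len(ev) == 1
        s, e = gt.swd_epochs[0]
        assert ev[0].start == pytest.approx(s, abs=0.3)
        assert ev[0].end == pytest.approx(e, abs=0.3)

    def test_short_train_rejected_by_duration_rule(self, rng):
        from ripplemap.synth import spike_wave_template

        fs = 2000.0
        x = rng.normal(0, 2, int(15 * fs))
        tmpl, _ = spike_wave_template(fs, 11.0, 300.0)
        for k in range(int(0.8 * 11)):  # only 0.8 s of train
            i = int((5 + k / 11.0) * fs)
            x[i: i + len(tmpl)] += tmpl[: len(x) - i]
        assert detect_swd(x, fs) == []

    def test_out_of_band_oscillation_ignored(self, rng):
        fs = 2000.0
        t = np.arange(int(15 * fs)) / fs
        x = 200 * np.sin(2 * np.pi * 6 * t) + rng.normal(0, 2, len(t))
        assert detect_swd(x, fs) == []

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            detect_swd(np.zeros(1000), fs=100.0)


class TestHFO:
    def test_injected_packets_detected_and_confirmed(self, single_channel_lesion):
        _, rec, gt = single_channel_lesion
        bs = segment_burst_suppression(rec)
        sup = [(e.start, e.end) for e in bs if e.kind == "suppression"]
        bur = [(e.start, e.end) for e in bs if e.kind == "burst"]
        events = detect_hfo(rec.samples[0], HFR, rec.fs, sup, burst_epochs=bur)
        assert len(gt.hfo_events) >= 3
        hits = sum(
            any(ev.start - 0.01 <= 0.5 * (s + e) <= ev.end + 0.01 for ev in events)
            for s, e in gt.hfo_events
        )
        assert hits / len(gt.hfo_events) >= 0.9
        assert all(ev.power_confirmed for ev in events)
        assert all(ev.n_cycles >= 4 for ev in events)

    def test_two_cycle_packet_rejected(self, rng):
        fs = 20_000.0
        n = int(30 * fs)
        t = np.arange(n) / fs
        cfg = SynthConfig(n_channels=1, duration=30.0, ripple_amp_profile=[1.0],
                          burst_rate=0, n_swd=0, seed=0)
        rec, _ = make_recording(cfg)
        x = rec.samples[0].copy()
        sig = rm.synth.noise_band_sigma(cfg, (300.0, 800.0))
        amp = packet_amplitude(8.0, sig)
        c = 15.0
        w = np.exp(-((t - c) ** 2) / (2 * (2 / (2.355 * 500)) ** 2))  # 2-cycle FWHM
        x += amp * w * np.cos(2 * np.pi * 500 * (t - c))
        base = auto_baseline_epochs(x, HFR, fs)
        events = detect_hfo(x, HFR, fs, base)
        assert not any(abs(0.5 * (e.start + e.end) - c) < 0.02 for e in events)

    def test_missing_baseline_errors(self, rng):
        with pytest.raises(ValueError, match="baseline"):
            detect_hfo(rng.normal(size=20_000), HFR, 20_000.0, [])

    def test_translation_equivariance(self, rng):
        fs = 20_000.0
        n = int(10 * fs)
        t = np.arange(n) / fs
        x = rng.normal(0, 5, n)
        c = 4.0
        w = np.exp(-((t - c) ** 2) / (2 * 0.007**2))  # ~8-cycle FWHM at 500 Hz
        x += 30 * w * np.cos(2 * np.pi * 500 * (t - c))
        shift = int(1.0 * fs)
        x2 = np.roll(x, shift)
        base = [(8.0, 10.0)]
        e1 = detect_hfo(x, HFR, fs, base)
        e2 = detect_hfo(x2, HFR, fs, base)
        assert len(e1) == len(e2) == 1
        assert e2[0].start - e1[0].start == pytest.approx(1.0, abs=0.002)

    def test_threshold_monotonicity(self, single_channel_lesion):
        _, rec, _ = single_channel_lesion
        bs = segment_burst_suppression(rec)
        sup = [(e.start, e.end) for e in bs if e.kind == "suppression"]
        counts = [
            len(detect_hfo(rec.samples[0], HFR, rec.fs, sup, k=k))
            for k in (2.0, 3.0, 4.0, 6.0, 9.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_events_restricted_to_bursts(self, single_channel_lesion):
        _, rec, _ = single_channel_lesion
        bs = segment_burst_suppression(rec)
        sup = [(e.start, e.end) for e in bs if e.kind == "suppression"]
        bur = [(e.start, e.end) for e in bs if e.kind == "burst"]
        events = detect_hfo(rec.samples[0], HFR, rec.fs, sup, burst_epochs=bur)
        for ev in events:
            mid = 0.5 * (ev.start + ev.end)
            assert any(s <= mid <= e for s, e in bur)


class TestPrevalence:
    def test_counts_layout(self):
        table = prevalence_table({
            "control": [True] + [False] * 11,
            "lesion": [True] * 12 + [False] * 8,
        })
        np.testing.assert_array_equal(table, [[1, 11], [12, 8]])

    def test_all_negative(self):
        table = prevalence_table({"control": [False] * 3, "lesion": [False] * 5})
        np.testing.assert_array_equal(table, [[0, 3], [0, 5]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            prevalence_table({"control": [], "lesion": [True]})


def test_epoch_event_validation():
    with pytest.raises(ValueError):
        EpochEvent("burst", 1.0, 1.0)
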