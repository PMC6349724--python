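import numpy as np
import pytest

from ripplemap.filters import Band, bandpass
from ripplemap.phase import (
    circular_mean_deg,
    phase_group_comparison,
    rayleigh_test,
    resultant_length,
    sfc,
    sfc_depth_correlation,
    spike_phase,
    spike_phase_histogram,
    zero_phase_timestamps,
)
from ripplemap.synth import SynthConfig, UnitSpec, make_spike_trains

FS = 20_000.0
HFR = Band("HFR", 300.0, 800.0)


def _tone(f0=500.0, dur=10.0, amp=10.0):
    t = np.arange(int(dur * FS)) / FS
    return amp * np.cos(2 * np.pi * f0 * t), t


def _locked_spikes(mu, kappa, dur=20.0, rate=150.0, seed=2, f0=500.0):
    t = np.arange(int(dur * FS)) / FS
    phase = np.degrees(2 * np.pi * f0 * t) % 360.0
    cfg = SynthConfig(
        n_channels=1, fs=FS, duration=dur, burst_rate=0, n_swd=0,
        ripple_amp_profile=[1.0],
        unit_specs=[UnitSpec(channel=0, rate_burst=rate, phase_mu=mu,
                             phase_kappa=kappa)],
    )
    times, phases, _ = make_spike_trains(cfg, phase, rng=np.random.default_rng(seed))
    return times[0], phases[0]


class TestCircular:
    def test_rotation_property(self, rng):
        ph = rng.vonmises(0.0, 2.0, 300)
        deg = np.degrees(ph) % 360
        for delta in (30.0, 123.0, 270.0):
            m1 = circular_mean_deg(deg)
            m2 = circular_mean_deg((deg + delta) % 360)
            diff = (m2 - m1 - delta) % 360
            assert min(diff, 360 - diff) < 1e-6
            assert resultant_length(deg) == pytest.approx(
                resultant_length((deg + delta) % 360)
            )

    def test_rayleigh_against_pingouin(self, rng):
        import pingouin as pg

        for kappa in (0.0, 0.5, 2.0):
            ph = np.degrees(rng.vonmises(1.0, kappa, 200)) % 360
            p_ours = rayleigh_test(ph)
            _, p_ref = pg.circ_rayleigh(np.radians(ph))
            assert p_ours == pytest.approx(p_ref, abs=1e-3)

    def test_single_spike_degenerate(self):
        assert resultant_length([123.0]) == pytest.approx(1.0)


class TestZeroPhase:
    def test_tone_yields_one_timestamp_per_cycle(self):
        x, _ = _tone(400.0, dur=5.0)
        ts = zero_phase_timestamps(bandpass(x, HFR, FS), FS)
        assert len(ts) == pytest.approx(400 * 5, abs=2)
        assert np.median(np.diff(ts)) == pytest.approx(1 / 400, abs=1 / FS)

    def test_zero_signal_empty(self):
        assert len(zero_phase_timestamps(np.zeros(10_000), FS)) == 0

    def test_timestamps_confined_to_packet(self, rng):
        dur, c = 5.0, 2.5
        t = np.arange(int(dur * FS)) / FS
        w = np.exp(-((t - c) ** 2) / (2 * 0.01**2))
        x = 8 * w * np.cos(2 * np.pi * 500 * t) + 0.3 * rng.normal(size=len(t))
        ts = zero_phase_timestamps(bandpass(x, HFR, FS), FS)
        assert len(ts) >= 10
        assert np.all(np.abs(ts - c) < 0.05)


class TestSpikePhase:
    def test_phase_convention_trough_is_180(self):
        x, t = _tone(500.0)
        filt = bandpass(x, HFR, FS)
        trough_times = t[np.argmin(filt[:1000])] + np.arange(100) / 500.0
        ph = spike_phase(trough_times, filt, FS)
        d = np.abs((ph - 180 + 180) % 360 - 180)
        assert np.median(d) < 20.0  # within one 20° bin of the trough

    def test_parameter_recovery_mu_and_rayleigh(self):
        times, _ = _locked_spikes(mu=300.0, kappa=4.0)
        x, _ = _tone(500.0, dur=20.0)
        rng = np.random.default_rng(0)
        lfp = x + 2.0 * rng.normal(size=len(x))
        ph = spike_phase(times, bandpass(lfp, HFR, FS), FS)
        assert len(ph) >= 500
        h = spike_phase_histogram(ph)
        err = abs(h.mean_angle - 300.0)
        assert min(err, 360 - err) <= 10.0
        assert h.rayleigh_p < 0.01

    def test_uniform_null_statistics(self):
        times, phases = _locked_spikes(mu=0.0, kappa=0.0, dur=10.0, rate=80.0)
        h = spike_phase_histogram(phases)
        # resultant length scales as ~1/sqrt(n) under uniformity
        assert h.resultant_length < 4.0 / np.sqrt(h.n_spikes)
        assert h.rayleigh_p > 0.001

    def test_low_n_flag(self):
        with pytest.warns(UserWarning, match="only"):
            h = spike_phase_histogram(np.array([10.0, 50.0, 300.0]))
        assert h.low_n
        assert h.firing_probability.sum() == pytest.approx(1.0)

    def test_histogram_probability_normalised(self, rng):
        h = spike_phase_histogram(rng.uniform(0, 360, 500))
        assert h.firing_probability.sum() == pytest.approx(1.0)
        assert len(h.bin_edges) == 19  # 18 bins of 20°


class TestSFC:
    def test_perfect_locking_limit(self):
        x, _ = _tone(400.0, dur=10.0)
        ts = zero_phase_timestamps(bandpass(x, Band("b", 300, 800), FS), FS)
        ts = ts[(ts > 0.2) & (ts < 9.8)][:300]
        prof = sfc(ts, x, FS)
        assert prof.sfc[np.argmin(np.abs(prof.freqs - 400))] == pytest.approx(1.0, abs=1e-6)

    def test_independent_spikes_bias_level(self, rng):
        lfp = rng.normal(0, 5, int(20 * FS))
        ts = np.sort(rng.uniform(0.2, 19.8, 400))
        prof = sfc(ts, lfp, FS)
        sel = (prof.freqs > 50) & (prof.freqs < 5000)
        # unlocked-spike bias floor ~ 1/n_spikes
        assert prof.sfc[sel].mean() == pytest.approx(1 / prof.n_spikes, rel=0.5)

    def test_gain_invariance(self, rng):
        lfp = rng.normal(0, 5, int(10 * FS))
        ts = np.sort(rng.uniform(0.2, 9.8, 200))
        a = sfc(ts, lfp, FS).sfc
        b = sfc(ts, 7.5 * lfp, FS).sfc
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_locked_exceeds_unlocked_in_band(self):
        rng = np.random.default_rng(1)
        x, _ = _tone(500.0, dur=20.0)
        lfp = x + 2.0 * rng.normal(size=len(x))
        t_inh, _ = _locked_spikes(mu=300.0, kappa=4.0, seed=3)
        t_exc, _ = _locked_spikes(mu=0.0, kappa=0.0, rate=40.0, seed=4)
        p_inh = sfc(t_inh, lfp, FS)
        p_exc = sfc(t_exc, lfp, FS)
        sel = (p_inh.freqs >= 300) & (p_inh.freqs <= 800)
        assert p_inh.sfc[sel].mean() > 3 * p_exc.sfc[sel].mean()

    def test_too_few_spikes_rejected(self, rng):
        with pytest.raises(ValueError, match="spikes"):
            sfc(np.array([1.0, 2.0]), rng.normal(size=int(5 * FS)), FS)


class TestDepthCorrelation:
    def _profile(self, peak, seed=0):
        from ripplemap.phase import SFCProfile

        rng = np.random.default_rng(seed)
        freqs = np.linspace(0, 1000, 101)
        vals = np.clip(rng.uniform(0, 0.05, 101), 0, 1)
        vals[50] = peak
        return SFCProfile(0, freqs, vals, 200.0, 100)

    def test_exactly_linear_gives_r_one(self):
        depths = np.array([100.0, 200.0, 300.0, 400.0])
        profs = [self._profile(0.1 + 0.002 * d, seed=i) for i, d in enumerate(depths)]
        r, p = sfc_depth_correlation(profs, depths)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_increasing_locking_with_depth_detected(self):
        rng = np.random.default_rng(5)
        depths = np.repeat(np.arange(1, 7) * 76.6, 2)
        profs = [self._profile(0.05 + 0.004 * d + rng.normal(0, 0.02), seed=i)
                 for i, d in enumerate(depths)]
        r, p = sfc_depth_correlation(profs, depths)
        assert r > 0
        assert p < 0.05

    def test_degenerate_inputs_rejected(self):
        profs = [self._profile(0.2, seed=i) for i in range(3)]
        with pytest.raises(ValueError, match="depth"):
            sfc_depth_correlation(profs, np.array([100.0, 100.0, 100.0]))
        with pytest.raises(ValueError, match=">= 3"):
            sfc_depth_correlation(profs[:2], np.array([1.0, 2.0]))


class TestGroupComparison:
    def _hists(self, mu, kappa, n_units, seed0=0, n_spk=400):
        out = []
        for i in range(n_units):
            rng = np.random.default_rng(seed0 + i)
            if kappa > 0:
                ph = np.degrees(rng.vonmises(np.radians(mu), kappa, n_spk)) % 360
            else:
                ph = rng.uniform(0, 360, n_spk)
            out.append(spike_phase_histogram(ph))
        return out

    def test_locked_vs_unlocked_contrast_at_300(self):
        res = phase_group_comparison({
            "INH": self._hists(300.0, 4.0, 4, seed0=10),
            "EXC": self._hists(0.0, 0.0, 5, seed0=20),
        })
        assert res.mask is not None and res.mask.sum() > 0
        assert any(lo <= 300.0 <= hi for lo, hi in res.significant_intervals)

    def test_null_comparison_empty_mask(self):
        res = phase_group_comparison({
            "INH": self._hists(0.0, 0.0, 4, seed0=30),
            "EXC": self._hists(0.0, 0.0, 4, seed0=40),
        })
        assert res.mask.sum() == 0

    def test_single_unit_descriptive_only(self):
        res = phase_group_comparison({
            "INH": self._hists(300.0, 4.0, 1),
            "EXC": self._hists(0.0, 0.0, 3),
        })
        assert res.mask is None and res.pvalues is None
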