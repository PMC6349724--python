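import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ripplemap.filters import Band, bandpass
from ripplemap.units import (
    class_fraction,
    classify_unit,
    detect_spikes,
    laminar_distribution,
    sort_units,
    waveform_features,
)
from ripplemap.synth import spike_template

FS = 20_000.0


def _embed(template, times, n, rng, noise_sd=1.0):
    x = rng.normal(0, noise_sd, n)
    tr = int(np.argmin(template))
    for t in times:
        i0 = int(round(t * FS)) - tr
        lo, hi = max(0, i0), min(n, i0 + len(template))
        x[lo:hi] += template[lo - i0: hi - i0]
    return x


class TestDetect:
    def test_injected_spikes_recovered(self, rng):
        tmpl, _ = spike_template(FS, 0.7, 0.4, 5.0)  # 5 SD spikes in unit noise
        true_t = np.sort(rng.uniform(0.1, 9.9, 100))
        true_t = true_t[np.concatenate([[True], np.diff(true_t) > 0.01])]
        x = _embed(tmpl, true_t, int(10 * FS), rng)
        det_t, snips = detect_spikes(x, FS)
        hits = sum(np.min(np.abs(det_t - t)) < 2e-4 for t in true_t)
        assert hits >= 0.98 * len(true_t)

    def test_noise_rate_bounded_by_rice_formula(self, rng):
        # Gaussian noise band-limited to 300-3000 Hz: the rate of maxima
        # below -2 sigma cannot exceed the level-crossing (Rice) rate
        x = bandpass(rng.normal(0, 1.0, int(10 * FS)), Band("mua", 300.0, 3000.0), FS)
        x /= x.std()
        det_t, _ = detect_spikes(x, FS, threshold_sd=2.0)
        f_lo, f_hi = 300.0, 3000.0
        # spectral RMS frequency of an ideal flat band
        f_rms = np.sqrt((f_hi**3 - f_lo**3) / (3 * (f_hi - f_lo)))
        rice = f_rms * np.exp(-(2.0**2) / 2)
        rate = len(det_t) / 10.0
        assert rate <= 1.2 * rice
        assert rate > 0.05 * rice  # and detection is not dead

    def test_dead_time_merges_close_spikes(self):
        tmpl, _ = spike_template(FS, 0.7, 0.4, 10.0)
        rng = np.random.default_rng(0)
        x = _embed(tmpl, [1.0, 1.0005], int(2 * FS), rng, noise_sd=0.5)
        det_t, _ = detect_spikes(x, FS, threshold_sd=4.0)
        near = det_t[np.abs(det_t - 1.0) < 2e-3]
        assert len(near) == 1  # the 0.5 ms pair collapses to one detection

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(100), fs=1000.0)


class TestSort:
    def _snippets(self, rng, amp_a=100.0, amp_b=50.0, n_each=200, same=False):
        ta, _ = spike_template(FS, 0.7, 0.4, amp_a)
        tb, _ = spike_template(FS, 0.7, 0.4, amp_b) if same else \
            spike_template(FS, 0.3, 0.15, amp_b)
        L = int(2e-3 * FS)
        def snip(tmpl):
            tr = int(np.argmin(tmpl))
            pre = int(0.35 * L)
            w = np.zeros(L)
            seg = tmpl[max(0, tr - pre): tr - pre + L]
            w[: len(seg)] = seg
            return w
        sa, sb = snip(ta), snip(tb)
        snips = np.stack([sa + rng.normal(0, 3.0, L) for _ in range(n_each)]
                         + [sb + rng.normal(0, 3.0, L) for _ in range(n_each)])
        times = np.arange(2 * n_each) * 0.01
        labels = np.array([0] * n_each + [1] * n_each)
        return snips, times, labels

    def test_two_templates_separated(self, rng):
        snips, times, labels = self._snippets(rng)
        units = sort_units(snips, times, FS)
        assert len(units) == 2
        # assignment accuracy against construction
        acc = 0
        for u in units:
            idx = np.isin(times, u.spike_times)
            maj = np.bincount(labels[idx]).argmax()
            acc += np.sum(labels[idx] == maj)
        assert acc / len(labels) >= 0.95

    def test_amplitude_ratio_two_to_one_separated(self, rng):
        snips, times, labels = self._snippets(rng, amp_a=100.0, amp_b=50.0, same=True)
        units = sort_units(snips, times, FS)
        assert len(units) == 2

    def test_single_template_one_unit(self, rng):
        snips, times, _ = self._snippets(rng, amp_a=80.0, amp_b=80.0, same=True)
        units = sort_units(snips, times, FS)
        assert len(units) == 1

    def test_too_few_snippets_warns(self, rng):
        snips, times, _ = self._snippets(rng, n_each=5)
        with pytest.warns(UserWarning):
            assert sort_units(snips, times, FS) == []

    def test_permutation_invariance(self, rng):
        snips, times, _ = self._snippets(rng)
        perm = rng.permutation(len(snips))
        u1 = sort_units(snips, times, FS)
        u2 = sort_units(snips[perm], times[perm], FS)
        assert len(u1) == len(u2)
        for a, b in zip(u1, u2):
            np.testing.assert_allclose(a.spike_times, b.spike_times)


class TestFeatures:
    @pytest.mark.parametrize("cls,tp,hw", [("EXC", 0.7, 0.4), ("INH", 0.3, 0.15)])
    def test_template_features_recovered(self, cls, tp, hw):
        tmpl, _ = spike_template(FS, tp, hw, 80.0)
        a, b, c = waveform_features(tmpl, FS)
        assert a == pytest.approx(tp, abs=1 / FS * 1e3)
        assert b == pytest.approx(hw, abs=1.2 / FS * 1e3)
        assert classify_unit((a, b, c)) == cls

    def test_scale_invariance(self):
        tmpl, _ = spike_template(FS, 0.5, 0.3, 40.0)
        f1 = waveform_features(tmpl, FS)
        f5 = waveform_features(5 * tmpl, FS)
        assert f1 == pytest.approx(f5)
        assert classify_unit(f1) == classify_unit(f5)

    def test_no_post_trough_peak_unclassified(self):
        w = -np.exp(-((np.arange(40) - 30) ** 2) / 8.0)  # trough at the end
        a, b, c = waveform_features(w, FS)
        assert np.isnan(c)
        assert classify_unit((a, b, c)) == "unclassified"


class TestClassify:
    def test_canonical_points(self):
        assert classify_unit((0.3, 0.15, 0.4)) == "INH"
        assert classify_unit((0.7, 0.4, 0.4)) == "EXC"

    def test_boundary_tie_goes_to_exc(self):
        b = 0.2
        a = 0.55 - 0.5 * b
        assert classify_unit((a, b, 0.5)) == "EXC"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.05, 1.5),
        b=st.floats(0.05, 1.0),
        gain=st.floats(0.1, 100.0),
    )
    def test_gain_never_flips_class(self, a, b, gain):
        # a, b are latencies/widths: unchanged by gain; c is a ratio
        tmpl, _ = spike_template(FS, a, b, 50.0)
        f = waveform_features(tmpl, FS)
        g = waveform_features(gain * tmpl, FS)
        assert classify_unit(f) == classify_unit(g)


class TestDistribution:
    def _unit(self, ch, cls):
        from ripplemap.units import Unit

        return Unit(0, ch, 0.0, np.array([0.0]), np.zeros((1, 4)), np.zeros(4),
                    (0.5, 0.3, 0.4), cls)

    def test_class_fractions_over_channel_ranges(self):
        units = [self._unit(c, "EXC") for c in [0, 1, 2, 0, 1, 2, 0, 4, 5]]
        units += [self._unit(c, "INH") for c in [3, 4, 5, 3, 4, 5, 0, 1]]
        counts = laminar_distribution(units)
        assert counts["EXC"].sum() == 9
        assert counts["INH"].sum() == 8
        assert class_fraction(units, "EXC", range(1, 4)) == pytest.approx(7 / 9)
        assert class_fraction(units, "INH", range(4, 7)) == pytest.approx(6 / 8)

    def test_empty_distribution(self):
        counts = laminar_distribution([])
        assert int(counts.to_numpy().sum()) == 0
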