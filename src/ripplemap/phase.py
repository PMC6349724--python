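"""Oscillation phase, spike-phase statistics and spike-field coherence.

Phase convention (cosine / analytic-signal angle): 0° is the positive
peak of the band-filtered trace, 90° the falling zero-crossing, 180°
the trough, 270° the rising zero-crossing.  Some figure conventions
place the origin elsewhere; ``origin_deg`` shifts all reported phases
and every output records the convention used.

Spike-field coherence uses the spike-triggered-average estimator:
SFC(f) = power spectrum of the STA divided by the mean power spectrum
of the individual spike-centred LFP segments (±100 ms, Hann-tapered).
It is bounded in [0, 1], reaches 1 for perfect locking, and has a bias
floor of ~1/n_spikes for unlocked spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats
from scipy.fft import next_fast_len
from scipy.signal import get_window, hilbert

from .filters import Band
from .stats import holm_sidak

__all__ = [
    "PhaseHistogram",
    "SFCProfile",
    "PhaseComparison",
    "circular_mean_deg",
    "resultant_length",
    "rayleigh_test",
    "zero_phase_timestamps",
    "spike_phase",
    "spike_phase_histogram",
    "sfc",
    "sfc_depth_correlation",
    "phase_group_comparison",
]


@dataclass
class PhaseHistogram:
    bin_edges: np.ndarray          # degrees, 0..360
    firing_probability: np.ndarray  # sums to 1
    n_spikes: int
    mean_angle: float              # degrees
    resultant_length: float        # [0, 1]
    rayleigh_p: float
    band: Band | None = None
    low_n: bool = False
    origin_deg: float = 0.0        # phase-convention offset applied

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class SFCProfile:
    unit_id: int
    freqs: np.ndarray
    sfc: np.ndarray                # in [0, 1]
    window_ms: float
    n_spikes: int
    estimator: str = "spike-triggered-average power ratio"

    def max_in(self, freq_range: tuple[float, float] | None = None) -> float:
        if freq_range is None:
            return float(self.sfc.max())
        sel = (self.freqs >= freq_range[0]) & (self.freqs <= freq_range[1])
        return float(self.sfc[sel].max())


@dataclass
class PhaseComparison:
    bin_centers: np.ndarray
    mean_probability: dict         # class -> per-bin mean firing probability
    pvalues: np.ndarray | None
    mask: np.ndarray | None
    significant_intervals: list = field(default_factory=list)  # (lo, hi) degrees


# ---------------------------------------------------------------------------
# circular statistics


def _to_rad(deg):
    return np.radians(np.asarray(deg, dtype=float))


def circular_mean_deg(phases_deg) -> float:
    """Circular mean direction, in degrees [0, 360)."""
    z = np.exp(1j * _to_rad(phases_deg)).mean()
    return float(np.degrees(np.angle(z)) % 360.0)


def resultant_length(phases_deg) -> float:
    """Mean resultant length R in [0, 1]; 1 = perfectly concentrated."""
    return float(np.abs(np.exp(1j * _to_rad(phases_deg)).mean()))


def rayleigh_test(phases_deg) -> float:
    """Rayleigh test p-value for non-uniformity of circular data
    (Zar's finite-n approximation of the Z = n·R² statistic)."""
    n = len(phases_deg)
    if n == 0:
        return 1.0
    r = resultant_length(phases_deg)
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# phase extraction


def _analytic(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    return hilbert(x, N=next_fast_len(n))[:n]


def zero_phase_timestamps(
    filtered: np.ndarray,
    fs: float,
    envelope_floor: float = 2.0,
) -> np.ndarray:
    """Per-cycle reference times at the positive peak (0°) of a
    band-filtered oscillation.

    Cycles are counted only where the band envelope exceeds
    ``envelope_floor`` times its median, which suppresses phase noise
    in silent stretches.  Crossing times are linearly interpolated.
    """
    analytic = _analytic(filtered)
    env = np.abs(analytic)
    if env.max() == 0:
        return np.empty(0)
    phase = np.angle(analytic)
    # floor suppresses phase noise in silent stretches; it is applied to
    # the envelope smoothed over ~one cycle of the dominant frequency
    # (which de-spikes the Rayleigh tail of noise-only stretches), and
    # capped so constant-envelope signals stay countable
    dphi = np.diff(np.unwrap(phase))
    f_dom = np.median(dphi) * fs / (2 * np.pi)
    if f_dom > 0:
        from scipy.ndimage import gaussian_filter1d

        env = gaussian_filter1d(env, max(1.0, 4.0 * fs / f_dom / 2.355))
    floor = min(envelope_floor * np.median(env), 0.5 * env.max())
    # upward crossings of phase 0 (negative -> non-negative, not the ±pi wrap)
    prev, cur = phase[:-1], phase[1:]
    cross = np.flatnonzero((prev < 0) & (cur >= 0) & (cur - prev < np.pi))
    frac = -prev[cross] / (cur[cross] - prev[cross])
    t = (cross + frac) / fs
    keep = env[cross] > floor
    return t[keep]


def spike_phase(
    spike_times: np.ndarray,
    filtered: np.ndarray,
    fs: float,
    origin_deg: float = 0.0,
) -> np.ndarray:
    """Instantaneous band phase at each spike time, degrees [0, 360).

    Interpolates the analytic signal (real and imaginary parts) at the
    spike times, so phases are sub-sample accurate.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    analytic = _analytic(filtered)
    tt = np.arange(len(filtered)) / fs
    re = np.interp(spike_times, tt, analytic.real)
    im = np.interp(spike_times, tt, analytic.imag)
    deg = np.degrees(np.arctan2(im, re))
    return (deg - origin_deg) % 360.0


def spike_phase_histogram(
    phases_deg: np.ndarray,
    n_bins: int = 18,
    band: Band | None = None,
    origin_deg: float = 0.0,
) -> PhaseHistogram:
    """Firing-probability histogram over phase with circular statistics.

    Fewer than 10 spikes still yields a histogram but sets ``low_n``.
    """
    phases_deg = np.asarray(phases_deg, dtype=float) % 360.0
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(phases_deg, bins=edges)
    n = len(phases_deg)
    prob = counts / n if n else np.zeros(n_bins)
    low_n = n < 10
    if low_n:
        warnings.warn(f"phase histogram built from only {n} spikes")
    return PhaseHistogram(
        bin_edges=edges,
        firing_probability=prob,
        n_spikes=n,
        mean_angle=circular_mean_deg(phases_deg) if n else np.nan,
        resultant_length=resultant_length(phases_deg) if n else 0.0,
        rayleigh_p=rayleigh_test(phases_deg),
        band=band,
        low_n=low_n,
        origin_deg=origin_deg,
    )


# ---------------------------------------------------------------------------
# spike-field coherence


def sfc(
    spike_times: np.ndarray,
    lfp: np.ndarray,
    fs: float,
    window_ms: float = 200.0,
    min_spikes: int = 50,
    unit_id: int = -1,
) -> SFCProfile:
    """Spike-field coherence from spike-centred LFP segments.

    SFC(f) = |spectrum of the STA|² / mean |spectrum of segments|²,
    with Hann-tapered ±window/2 segments around each spike.  Invariant
    to LFP gain; bounded in [0, 1] by the power-mean inequality.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    lfp = np.asarray(lfp, dtype=float)
    half = int(round(window_ms / 2 * 1e-3 * fs))
    centers = np.round(spike_times * fs).astype(int)
    centers = centers[(centers - half >= 0) & (centers + half < len(lfp))]
    if len(centers) < min_spikes:
        raise ValueError(
            f"SFC needs >= {min_spikes} spikes with full windows, got {len(centers)}"
        )
    length = 2 * half
    w = get_window("hann", length)
    segs = np.stack([lfp[c - half: c + half] for c in centers]) * w
    spec = np.fft.rfft(segs, axis=1)
    num = np.abs(spec.mean(axis=0)) ** 2
    den = np.mean(np.abs(spec) ** 2, axis=0)
    vals = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
    freqs = np.fft.rfftfreq(length, 1.0 / fs)
    return SFCProfile(
        unit_id=unit_id,
        freqs=freqs,
        sfc=np.clip(vals, 0.0, 1.0),
        window_ms=window_ms,
        n_spikes=len(centers),
    )


def sfc_depth_correlation(
    profiles: list[SFCProfile],
    depths: np.ndarray,
    freq_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Pearson correlation between per-unit maximum SFC and depth.

    Returns (r, two-sided p).  Requires >= 3 units and non-degenerate
    depths.
    """
    if len(profiles) < 3:
        raise ValueError("depth correlation needs >= 3 units")
    depths = np.asarray(depths, dtype=float)
    if np.std(depths) == 0:
        raise ValueError("zero variance in depths")
    peak = np.array([p.max_in(freq_range) for p in profiles])
    r, p = spstats.pearsonr(peak, depths)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# group comparison


def phase_group_comparison(
    histograms_by_class: dict[str, list[PhaseHistogram]],
    alpha: float = 0.05,
) -> PhaseComparison:
    """Per-phase-bin contrast of firing probability between two classes.

    Two-sample t-test per bin with Holm-Sidak correction across bins;
    reports the contiguous phase intervals covered by significant bins.
    With fewer than 2 units in a class the result is descriptive only
    (no test, ``mask`` is None).
    """
    classes = list(histograms_by_class)
    if len(classes) != 2:
        raise ValueError("phase comparison requires exactly two classes")
    mats = {}
    edges = None
    for cls in classes:
        hists = histograms_by_class[cls]
        if not hists:
            raise ValueError(f"class {cls!r} has no histograms")
        if edges is None:
            edges = hists[0].bin_edges
        mats[cls] = np.stack([h.firing_probability for h in hists])
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean_prob = {cls: mats[cls].mean(axis=0) for cls in classes}

    if min(len(histograms_by_class[c]) for c in classes) < 2:
        return PhaseComparison(centers, mean_prob, None, None, [])

    tt = spstats.ttest_ind(mats[classes[0]], mats[classes[1]], axis=0)
    pvals = np.nan_to_num(tt.pvalue, nan=1.0)
    reject, _ = holm_sidak(pvals, alpha)
    intervals = []
    in_run = False
    for i, r in enumerate(reject):
        if r and not in_run:
            lo = edges[i]
            in_run = True
        if in_run and (not r or i == len(reject) - 1):
            hi = edges[i + 1] if r else edges[i]
            intervals.append((float(lo), float(hi)))
            in_run = False
    return PhaseComparison(centers, mean_prob, pvals, reject, intervals)
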