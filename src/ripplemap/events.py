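"""Epileptiform event detection: burst-suppression, SWDs, HFOs.

Burst-suppression segmentation thresholds the smoothed 1–100 Hz
envelope at the midpoint of its bimodal amplitude distribution (with
hysteresis).  SWDs are epochs where 9–13 Hz power dominates the 1–50 Hz
range and a regular 10–12 Hz peak train is present, pruned to >= 1 s.
HFO candidates are sustained increases of the band-limited envelope
above a robust baseline, confirmed by a spectrographic in-band power
criterion; with a burst-suppression segmentation supplied, events are
restricted to burst epochs (HFOs do not occur during suppression).

Baseline statistics are robust (median / MAD-based SD) so that the
events themselves do not contaminate the reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .filters import Band, bandpass, envelope
from .sigio import Recording

__all__ = [
    "EpochEvent",
    "HFOEvent",
    "segment_burst_suppression",
    "detect_swd",
    "detect_hfo",
    "auto_baseline_epochs",
    "prevalence_table",
]


@dataclass
class EpochEvent:
    kind: str              # burst | suppression | SWD
    start: float           # s
    end: float             # s
    channel: int | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"epoch end {self.end} must exceed start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class HFOEvent:
    channel: int
    band: Band
    start: float
    end: float
    n_cycles: float
    peak_envelope_sd: float   # peak envelope in multiples of baseline robust SD
    power_confirmed: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


def _robust_stats(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    sd = float(np.median(np.abs(x - med)) / 0.6745)
    return med, sd


def _epochs_from_mask(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def _two_means(x: np.ndarray, iters: int = 30) -> tuple[float, float]:
    """1-D 2-means on a subsample; returns sorted cluster centres."""
    lo, hi = np.percentile(x, [10, 90])
    c = np.array([lo, hi], dtype=float)
    for _ in range(iters):
        mid = c.mean()
        left = x[x <= mid]
        right = x[x > mid]
        if len(left) == 0 or len(right) == 0:
            break
        new = np.array([left.mean(), right.mean()])
        if np.allclose(new, c):
            break
        c = new
    return float(c[0]), float(c[1])


# ---------------------------------------------------------------------------
# burst-suppression


def segment_burst_suppression(
    rec: Recording | np.ndarray,
    fs: float | None = None,
    channel: int = 0,
    smooth_s: float = 0.05,
    hysteresis: float = 0.2,
    min_burst_s: float = 0.1,
    min_suppression_s: float = 0.2,
    min_burst_amplitude: float = 30.0,
) -> list[EpochEvent]:
    """Segment a recording into alternating burst and suppression epochs.

    The 1–100 Hz envelope, smoothed over ``smooth_s``, is thresholded at
    the midpoint (in log amplitude) of its two histogram modes with
    ±``hysteresis`` relative hysteresis.  If the envelope is unimodal
    the whole recording is one epoch: a burst when the median envelope
    exceeds ``min_burst_amplitude`` (µV), suppression otherwise.
    """
    if isinstance(rec, Recording):
        x, fs = rec.samples[channel], rec.fs
    else:
        x = np.asarray(rec, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare signal")
    duration = len(x) / fs
    if duration < 5.0:
        raise ValueError("burst-suppression segmentation needs >= 5 s of signal")
    if np.std(x) == 0:
        warnings.warn("flat signal: returning a single suppression epoch")
        return [EpochEvent("suppression", 0.0, duration)]

    lf = bandpass(x, Band("lfp", 1.0, 100.0), fs)
    env = uniform_filter1d(envelope(lf), max(1, int(round(smooth_s * fs))))
    log_env = np.log10(env + 1e-12)
    sub = log_env[:: max(1, int(fs // 200))]  # ~200 Hz subsample for clustering
    c0, c1 = _two_means(sub)

    if c1 - c0 < 0.2:  # unimodal: less than a factor ~1.6 between modes
        kind = "burst" if np.median(env) > min_burst_amplitude else "suppression"
        return [EpochEvent(kind, 0.0, duration)]

    thr = 10 ** (0.5 * (c0 + c1))
    hi, lo = thr * (1 + hysteresis / 2), thr * (1 - hysteresis / 2)
    # hysteresis via state propagation: between the two levels, keep the
    # previous state (ffill of the last decisive crossing)
    decisive = (env > hi) | (env < lo)
    state_at = env > hi
    idx = np.where(decisive, np.arange(len(env)), 0)
    np.maximum.accumulate(idx, out=idx)
    mask = state_at[idx]

    bursts = [
        (s, e) for s, e in _epochs_from_mask(mask, fs) if e - s >= min_burst_s
    ]
    # absorb too-short suppressions into the surrounding bursts
    merged = []
    for s, e in bursts:
        if merged and s - merged[-1][1] < min_suppression_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    t = 0.0
    for s, e in merged:
        if s > t:
            events.append(EpochEvent("suppression", t, s))
        events.append(EpochEvent("burst", s, e))
        t = e
    if t < duration:
        events.append(EpochEvent("suppression", t, duration))
    return events


# ---------------------------------------------------------------------------
# spike-wave discharges


def detect_swd(
    x: np.ndarray,
    fs: float,
    freq_range: tuple[float, float] = (9.0, 13.0),
    ratio_threshold: float = 0.4,
    min_duration: float = 1.0,
    min_peaks: int = 8,
    rate_range: tuple[float, float] = (10.0, 12.0),
    spacing_tol: float = 0.2,
    merge_gap_s: float = 0.2,
) -> list[EpochEvent]:
    """Detect spike-wave discharges: >= 1 s epochs of repetitive
    10–12 Hz spike-wave patterns above baseline activity.

    An epoch qualifies when the (9–13 Hz)/(1–50 Hz) power ratio exceeds
    ``ratio_threshold`` and a regular train of >= ``min_peaks`` spike
    deflections with 10–12 Hz spacing (±``spacing_tol``) is present.
    """
    if fs < 200:
        raise ValueError("detect_swd requires fs >= 200 Hz")
    x = np.asarray(x, dtype=float)
    smooth = max(1, int(round(0.1 * fs)))
    e_band = gaussian_filter1d(envelope(bandpass(x, Band("swd", *freq_range), fs)) ** 2,
                               smooth)
    e_broad = gaussian_filter1d(envelope(bandpass(x, Band("broad", 1.0, 50.0), fs)) ** 2,
                                smooth)
    ratio = e_band / (e_broad + 1e-12)
    mask = ratio > ratio_threshold
    epochs = _epochs_from_mask(mask, fs)
    # merge close epochs, then prune short ones
    merged = []
    for s, e in epochs:
        if merged and s - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    merged = [(s, e) for s, e in merged if e - s >= min_duration]

    # short kernel (half a cycle of the low edge) so the periodic train is
    # not smeared outward by the filter's own support
    lf = bandpass(x, Band("spk", 5.0, 45.0), fs, cycles=0.5)
    out = []
    iso_lo = (1.0 - spacing_tol) / rate_range[1]
    iso_hi = (1.0 + spacing_tol) / rate_range[0]
    for s, e in merged:
        # pad so edge troughs keep their full prominence
        pad = 0.15
        i0 = max(0, int((s - pad) * fs))
        seg = lf[i0: min(len(lf), int((e + pad) * fs))]
        prom = 0.7 * np.std(lf[int(s * fs): int(e * fs)])
        peaks, _ = sps.find_peaks(-seg, prominence=prom,
                                  distance=max(1, int(iso_lo * fs)))
        # keep peaks within the candidate epoch (±50 ms); peak indices
        # stay in segment coordinates, peak_t in absolute seconds
        peak_t = (peaks + i0) / fs
        inside = (peak_t >= s - 0.05) & (peak_t <= e + 0.05)
        peaks, peak_t = peaks[inside], peak_t[inside]
        if len(peaks) < min_peaks:
            continue
        isi = np.diff(peaks) / fs
        good = (isi >= iso_lo) & (isi <= iso_hi)
        # a single missed trough shows as a double-period gap; let it
        # bridge a run without counting toward regularity
        bridge = (isi >= 2 * iso_lo) & (isi <= 2 * iso_hi)
        if not len(isi) or np.mean(good | bridge) < 0.7:
            continue
        # the longest (bridged) run of regularly spaced troughs defines
        # the discharge; this sharpens the smeared power-ratio boundaries
        # and ignores stray deflections at the candidate edges
        best_len, best_lo = 0, 0
        run_lo = 0
        for i, ok_isi in enumerate(good | bridge):
            if not ok_isi:
                run_lo = i + 1
            elif i - run_lo + 1 > best_len:
                best_len, best_lo = i - run_lo + 1, run_lo
        n_good = int(np.sum(good[best_lo: best_lo + best_len]))
        if n_good + 1 < min_peaks:
            continue
        run = peaks[best_lo: best_lo + best_len + 1]
        run_t = peak_t[best_lo: best_lo + best_len + 1]
        # trim shallow deflections at the run edges — stray burst-LFP
        # troughs that happened to fall at a compatible spacing
        depth_floor = 0.6 * float(np.median(-seg[run]))
        while len(run) and -seg[run[0]] < depth_floor:
            run, run_t = run[1:], run_t[1:]
        while len(run) and -seg[run[-1]] < depth_floor:
            run, run_t = run[:-1], run_t[:-1]
        if len(run) < min_peaks:
            continue
        half_period = 0.5 * float(np.median(np.diff(run_t)))
        t0 = run_t[0] - half_period
        t1 = run_t[-1] + half_period
        if t1 - t0 >= min_duration:
            out.append(EpochEvent("SWD", t0, t1))
    return out


# ---------------------------------------------------------------------------
# high-frequency oscillations


def auto_baseline_epochs(
    x: np.ndarray, band: Band, fs: float, window_s: float = 0.5, quantile: float = 0.25
) -> list[tuple[float, float]]:
    """Quietest-quartile windows of the band envelope, for use as a
    baseline when no suppression segmentation is available."""
    env = envelope(bandpass(x, band, fs))
    w = int(round(window_s * fs))
    n_win = len(env) // w
    if n_win < 4:
        raise ValueError("signal too short for baseline estimation")
    med = np.median(env[: n_win * w].reshape(n_win, w), axis=1)
    keep = np.flatnonzero(med <= np.quantile(med, quantile))
    return [(i * w / fs, (i + 1) * w / fs) for i in keep]


def detect_hfo(
    x: np.ndarray,
    band: Band,
    fs: float,
    baseline_epochs: list[tuple[float, float]],
    burst_epochs: list[tuple[float, float]] | None = None,
    k: float = 3.0,
    k_edge: float = 1.5,
    min_cycles: float = 4.0,
    delta_db: float = 6.0,
    smooth_cycles: float = 8.0,
    channel: int = 0,
) -> list[HFOEvent]:
    """Detect band-limited oscillation events against a robust baseline.

    Detection runs on the band power smoothed over ``smooth_cycles`` of the
    band-centre frequency (a near-matched filter for the canonical
    ripple-packet width): a candidate is a region where smoothed power
    stays above median + ``k_edge``·SD, peaks above median + ``k``·SD,
    and lasts >= ``min_cycles`` cycles.  Candidates are confirmed when their
    mean in-band power exceeds the baseline median by ``delta_db`` dB
    (the spectrographic check); only confirmed events are returned.
    With ``burst_epochs`` given, events outside bursts are discarded.
    """
    if not baseline_epochs:
        raise ValueError("baseline epochs are required for HFO detection")
    x = np.asarray(x, dtype=float)
    fc = band.center
    xb = bandpass(x, band, fs)
    env = envelope(xb)
    power = env**2
    sig_smooth = max(1.0, smooth_cycles / 2.355 * fs / fc)
    p_s = gaussian_filter1d(power, sig_smooth)

    base_idx = np.concatenate([
        np.arange(int(round(s * fs)), int(round(e * fs)))
        for s, e in baseline_epochs
    ])
    base_idx = base_idx[(base_idx >= 0) & (base_idx < len(x))]
    if base_idx.size < 10:
        raise ValueError("baseline epochs too short")
    med_p, sd_p = _robust_stats(p_s[base_idx])
    med_e, sd_e = _robust_stats(env[base_idx])
    ref_power = float(power[base_idx].mean())
    if sd_p == 0 or sd_e == 0:
        return []
    peak_thr = med_p + k * sd_p
    edge_thr = med_p + k_edge * sd_p
    min_dur = min_cycles / fc

    events: list[HFOEvent] = []
    for s, e in _epochs_from_mask(p_s > edge_thr, fs):
        if e - s < min_dur:
            continue
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        region = slice(i0, max(i1, i0 + 1))
        if p_s[region].max() < peak_thr:
            continue
        # cycle rule, amplitude-invariant: the event must contain
        # min_cycles oscillation peaks above half its own peak envelope
        # (a strong but brief transient cannot buy duration with amplitude)
        margin = int(round(2 * fs / fc))
        iw0, iw1 = max(0, i0 - margin), min(len(xb), i1 + margin)
        half_height = 0.5 * env[region].max()
        pk, _ = sps.find_peaks(xb[iw0:iw1], height=half_height,
                               distance=max(1, int(0.5 * fs / band.high)))
        if len(pk) < min_cycles:
            continue
        # spectrographic confirmation: peak in-band power (cycle-smoothed)
        # during the event must rise delta_db above the baseline mean power
        peak_db = 10.0 * np.log10(p_s[region].max() / max(ref_power, 1e-30))
        if peak_db < delta_db:
            continue
        if burst_epochs is not None:
            mid = 0.5 * (s + e)
            if not any(bs <= mid <= be for bs, be in burst_epochs):
                continue
        peak_sd = (env[region].max() - med_e) / sd_e
        events.append(
            HFOEvent(
                channel=channel,
                band=band,
                start=s,
                end=e,
                n_cycles=(e - s) * fc,
                peak_envelope_sd=float(peak_sd),
                power_confirmed=True,
            )
        )
    return events


def prevalence_table(flags_by_group: dict[str, list[bool]]) -> np.ndarray:
    """2x2 counts [[control+, control-], [lesion+, lesion-]].

    A recording is positive when it carries at least one confirmed HFO
    event above 100 Hz on any cortical channel (the caller computes the
    flag); rows follow control-then-lesion order when those labels are
    present, insertion order otherwise.
    """
    keys = list(flags_by_group)
    if set(keys) >= {"control", "lesion"}:
        keys = ["control", "lesion"] + [k for k in keys if k not in ("control", "lesion")]
    table = []
    for g in keys:
        flags = list(flags_by_group[g])
        if not flags:
            raise ValueError(f"group {g!r} has no recordings")
        pos = int(sum(bool(f) for f in flags))
        table.append([pos, len(flags) - pos])
    return np.asarray(table, dtype=int)
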