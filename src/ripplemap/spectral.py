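"""Spectral mapping: PSD, laminar power maps, coherence maps,
perievent spectrograms.

Power is Welch-estimated (0.5 s Hann windows, 50 % overlap by default,
i.e. 2 Hz resolution) and reported as 10·log10 of the density in
µV²/Hz.  The dB reference is arbitrary — only differences between
groups and the significance masks over them are comparable quantities.
Group comparisons are per-(frequency, channel) two-sample t-tests on dB
values with step-down Sidak (Holm-Sidak) correction across the whole
map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .sigio import Recording
from .stats import holm_sidak

__all__ = [
    "SpectralMap",
    "CoherenceMap",
    "PerieventResult",
    "psd",
    "laminar_map",
    "coherence_map",
    "perievent_spectrogram",
]

_TINY = 1e-30


@dataclass
class SpectralMap:
    freqs: np.ndarray          # Hz
    channels: np.ndarray       # channel indices (0-based)
    values: np.ndarray         # dB, (freq x channel)
    n: int                     # recordings per cell
    dispersion: np.ndarray | None = None  # per-cell SE of the mean

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectral map values must be finite")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class CoherenceMap:
    freqs: np.ndarray
    channels: np.ndarray
    values: np.ndarray         # magnitude-squared coherence in [0, 1]
    reference_channel: int

    def __post_init__(self) -> None:
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("coherence values must lie in [0, 1]")


@dataclass
class PerieventResult:
    times: np.ndarray          # s, relative to the event (0 = event)
    freqs: np.ndarray
    mean_db: np.ndarray        # (freq x time)
    pvalues: np.ndarray        # per-cell p vs the t=0 bin
    mask: np.ndarray           # Holm-Sidak rejections
    n_events: int
    n_dropped: int


def psd(
    segment: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    overlap: float = 0.5,
    return_linear: bool = False,
):
    """Welch power spectral density of a 1-D segment, in dB (10·log10).

    With ``return_linear`` the density in µV²/Hz is returned as a third
    element; integrating it over frequency recovers the signal variance
    (Parseval).
    """
    segment = np.asarray(segment, dtype=float)
    nperseg = int(round(window_s * fs))
    if len(segment) < nperseg:
        raise ValueError(
            f"segment of {len(segment)} samples shorter than one "
            f"{nperseg}-sample Welch window"
        )
    f, p = sps.welch(
        segment, fs, window="hann", nperseg=nperseg, noverlap=int(nperseg * overlap)
    )
    db = 10.0 * np.log10(p + _TINY)
    if return_linear:
        return f, db, p
    return f, db


def _recording_map(rec: Recording, segments, window_s: float, freq_sel=None):
    """Per-channel Welch dB map averaged (in linear units) over segments."""
    mats = []
    for s, e in segments:
        i0, i1 = int(round(s * rec.fs)), int(round(e * rec.fs))
        if i1 - i0 < int(round(window_s * rec.fs)):
            continue
        f, p = sps.welch(
            rec.samples[:, i0:i1],
            rec.fs,
            window="hann",
            nperseg=int(round(window_s * rec.fs)),
            noverlap=int(round(window_s * rec.fs)) // 2,
            axis=-1,
        )
        mats.append(p)
    if not mats:
        raise ValueError("no usable segments of at least one Welch window")
    p_mean = np.mean(mats, axis=0)  # (channel x freq)
    return f, 10.0 * np.log10(p_mean.T + _TINY)  # (freq x channel)


def laminar_map(
    recordings_by_group: dict[str, list[Recording]],
    freq_range: tuple[float, float] = (1.0, 800.0),
    segmenter=None,
    window_s: float = 0.5,
    alpha: float = 0.05,
) -> dict:
    """Group-average laminar power maps, their difference, and a
    Holm-Sidak-corrected significance mask.

    ``segmenter`` maps a Recording to a list of (start, end) analysis
    segments (e.g. burst epochs); by default the whole recording is one
    segment.  The difference map is lesion − control when those group
    labels are present.  Each (frequency, channel) cell is compared
    between groups with a two-sample t-test on dB values; the Holm-Sidak
    family is the full set of cells.
    """
    groups = list(recordings_by_group)
    if len(groups) != 2:
        raise ValueError("laminar_map compares exactly two groups")
    if set(groups) >= {"control", "lesion"}:
        groups = ["control", "lesion"]
    for g in groups:
        if len(recordings_by_group[g]) < 2:
            raise ValueError(f"group {g!r} needs >= 2 recordings")
    if segmenter is None:
        segmenter = lambda rec: [(0.0, rec.duration)]  # noqa: E731

    per_group = {}
    freqs_ref = None
    for g in groups:
        stack = []
        for rec in recordings_by_group[g]:
            f, db = _recording_map(rec, segmenter(rec), window_s)
            if freqs_ref is None:
                freqs_ref = f
            elif len(f) != len(freqs_ref) or not np.allclose(f, freqs_ref):
                raise ValueError("recordings have unmatched frequency grids")
            stack.append(db)
        per_group[g] = np.stack(stack)  # (rec x freq x channel)

    sel = (freqs_ref >= freq_range[0]) & (freqs_ref <= freq_range[1])
    freqs = freqs_ref[sel]
    channels = np.arange(per_group[groups[0]].shape[2])
    maps = {}
    for g in groups:
        vals = per_group[g][:, sel, :]
        maps[g] = SpectralMap(
            freqs=freqs,
            channels=channels,
            values=vals.mean(axis=0),
            n=vals.shape[0],
            dispersion=vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0]),
        )
    a, b = per_group[groups[0]][:, sel, :], per_group[groups[1]][:, sel, :]
    diff = SpectralMap(
        freqs=freqs,
        channels=channels,
        values=b.mean(axis=0) - a.mean(axis=0),
        n=min(a.shape[0], b.shape[0]),
    )
    tt = spstats.ttest_ind(b, a, axis=0)
    pvals = np.nan_to_num(tt.pvalue, nan=1.0)
    reject, _ = holm_sidak(pvals.ravel(), alpha)
    return {
        "groups": groups,
        "maps": maps,
        "difference": diff,
        "pvalues": pvals,
        "mask": reject.reshape(pvals.shape),
    }


def coherence_map(
    rec: Recording,
    reference: int = 0,
    window_s: float = 0.5,
    overlap: float = 0.5,
    freq_range: tuple[float, float] | None = None,
) -> CoherenceMap:
    """Magnitude-squared coherence of every channel against a reference
    channel (channel 1 by convention: the most superficial contact).

    Requires at least 4 Welch windows — the single-window coherence
    estimate is identically 1.
    """
    nperseg = int(round(window_s * rec.fs))
    noverlap = int(nperseg * overlap)
    n_win = (rec.n_samples - noverlap) // (nperseg - noverlap)
    if n_win < 4:
        raise ValueError(f"coherence needs >= 4 Welch windows, got {n_win}")
    ref = rec.samples[reference]
    f, cxy = sps.coherence(
        ref[None, :], rec.samples, fs=rec.fs, window="hann",
        nperseg=nperseg, noverlap=noverlap, axis=-1,
    )
    cxy = np.clip(cxy, 0.0, 1.0)
    cxy[reference] = 1.0  # self-coherence, exactly
    if freq_range is not None:
        sel = (f >= freq_range[0]) & (f <= freq_range[1])
        f, cxy = f[sel], cxy[:, sel]
    return CoherenceMap(
        freqs=f, channels=np.arange(rec.n_channels), values=cxy.T,
        reference_channel=reference,
    )


def perievent_spectrogram(
    x: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window_s: float = 0.2,
    nperseg_s: float = 0.025,
    step_s: float = 0.005,
    freq_range: tuple[float, float] = (100.0, 1000.0),
    alpha: float = 0.05,
) -> PerieventResult:
    """Event-triggered average spectrogram with per-bin statistics.

    Short-time spectrograms (25 ms windows, 5 ms steps by default) are
    aligned to each event and averaged.  For every frequency bin, each
    time bin is compared against the t = 0 bin with a paired t-test
    across events, Holm-Sidak corrected over all (frequency, time)
    cells.  Events closer than half a window to an edge are dropped
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    half = int(round(window_s / 2 * fs))
    if 2 * half > len(x):
        raise ValueError("perievent window exceeds the recording length")
    nperseg = int(round(nperseg_s * fs))
    step = int(round(step_s * fs))

    centers = np.round(event_times * fs).astype(int)
    ok = (centers - half >= 0) & (centers + half <= len(x))
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} events too close to the edges")
    centers = centers[ok]
    if len(centers) < 5:
        raise ValueError("perievent spectrogram needs >= 5 usable events")

    specs = []
    for c in centers:
        seg = x[c - half: c + half]
        f, tt, S = sps.spectrogram(
            seg, fs, window="hann", nperseg=nperseg, noverlap=nperseg - step
        )
        specs.append(10.0 * np.log10(S + _TINY))
    specs = np.stack(specs)  # (event x freq x time)
    times = tt - window_s / 2  # scipy returns window centres; re-reference to the event

    sel = (f >= freq_range[0]) & (f <= freq_range[1])
    f, specs = f[sel], specs[:, sel, :]
    i0 = int(np.argmin(np.abs(times)))

    ref = specs[:, :, i0][:, :, None]
    tstat = spstats.ttest_rel(specs, np.broadcast_to(ref, specs.shape), axis=0)
    pvals = np.nan_to_num(tstat.pvalue, nan=1.0)
    pvals[:, i0] = 1.0  # reference column compared with itself
    reject, _ = holm_sidak(pvals.ravel(), alpha)
    return PerieventResult(
        times=times,
        freqs=f,
        mean_db=specs.mean(axis=0),
        pvalues=pvals,
        mask=reject.reshape(pvals.shape),
        n_events=len(centers),
        n_dropped=n_dropped,
    )
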