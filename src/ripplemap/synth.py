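"""Synthetic laminar recordings with known ground truth.

The generator is phenomenological, not biophysical: it composes the
statistical structures the downstream analyses assume and reports
exactly where it put them.

A synthetic recording contains

* alternating burst/suppression epochs (anesthesia-induced B-S), where
  only the low-frequency (<100 Hz) share of the 1/f background is
  amplitude-modulated — the high-frequency noise floor is stationary,
  as in real recordings where suppression silences synaptic currents
  but not the wideband noise floor;
* optional spike-wave discharges (SWDs): a 10–12 Hz train of a sharp
  biphasic transient plus a slow after-wave, lasting >= 1 s;
* ripple packets (default 300–800 Hz band) whose amplitude is locked to
  the SWD spike troughs with a configurable modulation depth, plus
  discrete packets scattered through bursts; packet amplitudes are
  calibrated in multiples of the robust SD of the baseline ripple-band
  envelope, the same scale an HFO detector measures;
* a laminar amplitude gradient, strongest superficially;
* spike trains of two waveform classes (broad "EXC" / narrow "INH"),
  rate-modulated by the burst mask and phase-thinned against the ripple
  carrier by a von Mises acceptance rule.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .filters import Band
from .sigio import Recording, assign_laminae, electrode_depths

__all__ = [
    "SynthConfig",
    "UnitSpec",
    "GroundTruth",
    "make_recording",
    "make_spike_trains",
    "spike_template",
    "spike_wave_template",
    "laminar_profile",
    "noise_band_sigma",
    "packet_amplitude",
    "control_config",
    "lesion_config",
    "write_ground_truth_csv",
]

# canonical waveform-class templates; chosen to fall on opposite sides of
# the narrow/broad-spiking classifier boundary
EXC_SHAPE = {"trough_peak": 0.7, "waveform_halfwidth": 0.4}   # ms
INH_SHAPE = {"trough_peak": 0.3, "waveform_halfwidth": 0.15}  # ms

# Rayleigh-envelope constants for a Gaussian band-limited process with
# per-quadrature SD sigma: median and MAD/0.6745 of the Hilbert envelope
RAYLEIGH_MEDIAN = math.sqrt(2.0 * math.log(2.0))  # 1.1774 sigma
RAYLEIGH_ROBUST_SD = 0.6645  # numerically solved MAD(Rayleigh)/0.6745


@dataclass
class UnitSpec:
    """Ground-truth description of one synthetic single unit."""

    channel: int
    cell_class: str = "EXC"
    rate_burst: float = 20.0        # Hz, nominal rate inside bursts (pre-thinning)
    rate_suppression: float = 0.0   # Hz, outside bursts
    phase_mu: float = 0.0           # degrees, preferred ripple phase
    phase_kappa: float = 0.0        # von Mises concentration; 0 = unlocked
    waveform_halfwidth: float | None = None  # ms; default from cell_class
    trough_peak: float | None = None         # ms
    amplitude: float = 80.0         # µV trough depth of the injected waveform

    def __post_init__(self) -> None:
        if self.cell_class not in ("EXC", "INH"):
            raise ValueError(f"cell_class must be EXC or INH, got {self.cell_class!r}")
        if self.phase_kappa < 0:
            raise ValueError(f"phase_kappa must be >= 0, got {self.phase_kappa}")
        if not (self.rate_burst >= self.rate_suppression >= 0):
            raise ValueError("need rate_burst >= rate_suppression >= 0")
        shape = EXC_SHAPE if self.cell_class == "EXC" else INH_SHAPE
        if self.waveform_halfwidth is None:
            self.waveform_halfwidth = shape["waveform_halfwidth"]
        if self.trough_peak is None:
            self.trough_peak = shape["trough_peak"]


@dataclass
class SynthConfig:
    """Parameters of a synthetic laminar recording.

    Amplitudes are in µV.  ``*_amp_sd`` parameters are in multiples of
    the robust SD of the baseline ripple-band envelope (see
    :func:`packet_amplitude`), commensurate with detector thresholds.
    """

    n_channels: int = 16
    fs: float = 20_000.0
    duration: float = 30.0
    group: str = "lesion"
    # burst-suppression
    burst_rate: float = 0.25            # burst cycles per second (0 = no modulation)
    burst_dur: tuple = (0.5, 2.0)       # s, uniform draw
    suppression_floor: float = 0.15     # relative LFP amplitude during suppression
    burst_lfp_std: float = 40.0         # µV, shared 1–15 Hz burst activity
    # spike-wave discharges
    n_swd: int = 1
    swd_freq: float = 11.0              # Hz
    swd_dur: float = 2.0                # s, must be >= 1
    swd_amp: float = 300.0              # µV spike-trough depth
    # ripples
    ripple_band: tuple = (300.0, 800.0)
    ripple_freq: float = 500.0          # carrier Hz (within ripple_band)
    ripple_amp_profile: np.ndarray | None = None  # per-channel gain, superficial-weighted
    cfc_depth: float = 1.0              # [0,1] modulation of ripple amp by SWD phase
    swd_ripple_amp_sd: float = 6.0
    swd_ripple_cycles: float = 8.0      # FWHM of the packet envelope, in cycles
    hfo_rate: float = 0.0               # discrete packets per second of burst time
    hfo_amp_sd: float = 6.0
    hfo_cycles: float = 8.0
    burst_ripple_amp_sd: float = 0.0    # continuous in-burst ripple (phase analyses)
    # background
    noise_exponent: float = 1.0         # 1/f^a slope of the background
    noise_std: float = 15.0             # µV, total background SD
    line_freq: float | None = None
    line_amp: float = 5.0
    # units
    unit_specs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.ripple_band[1]:
            raise ValueError(
                f"fs={self.fs} below Nyquist for ripple band {self.ripple_band}"
            )
        if not 0.0 <= self.cfc_depth <= 1.0:
            raise ValueError(f"cfc_depth must be in [0,1], got {self.cfc_depth}")
        if self.n_swd > 0 and self.swd_dur < 1.0:
            raise ValueError("SWD epochs must last at least 1 s")
        if self.burst_rate > 0 and self.duration < self.burst_dur[0] + 0.5:
            raise ValueError(
                f"duration {self.duration} s too short to hold one burst cycle"
            )
        if self.n_swd > 0 and self.duration < self.swd_dur + 1.0:
            raise ValueError("duration too short to hold the requested SWD")
        if self.ripple_amp_profile is None:
            self.ripple_amp_profile = laminar_profile(self.n_channels)
        self.ripple_amp_profile = np.asarray(self.ripple_amp_profile, dtype=float)
        if len(self.ripple_amp_profile) != self.n_channels:
            raise ValueError("ripple_amp_profile length must equal n_channels")

    @classmethod
    def from_file(cls, path: str | Path) -> "SynthConfig":
        """Read a config from YAML or JSON."""
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "unit_specs" in data:
            data["unit_specs"] = [UnitSpec(**u) for u in data["unit_specs"]]
        for key in ("burst_dur", "ripple_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ripple_amp_profile"] = list(map(float, self.ripple_amp_profile))
        return d


@dataclass
class GroundTruth:
    """Manifest of everything the generator injected."""

    burst_epochs: list
    suppression_epochs: list
    swd_epochs: list
    hfo_events: list                 # (start, end) of discrete burst packets
    swd_spike_times: np.ndarray      # trough times of SWD spike deflections
    unit_spike_times: dict           # unit id -> times (s)
    unit_true_phase: dict            # unit id -> accepted ripple phase per spike (deg)
    unit_true_class: dict            # unit id -> EXC | INH


def laminar_profile(n_channels: int) -> np.ndarray:
    """Default laminar gain: linear falloff 1 -> 0.3 over the 12 cortical
    channels, 0.15 subcortically."""
    prof = np.full(n_channels, 0.15)
    n_cortical = min(12, n_channels)
    if n_cortical > 1:
        prof[:n_cortical] = np.linspace(1.0, 0.3, n_cortical)
    else:
        prof[:n_cortical] = 1.0
    return prof


def control_config(seed: int = 0, **overrides) -> SynthConfig:
    """A control-like recording: B-S present, no SWDs, no ripple packets."""
    kw = dict(group="control", n_swd=0, hfo_rate=0.0, seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


def lesion_config(seed: int = 0, **overrides) -> SynthConfig:
    """A lesion-like recording: B-S plus one SWD and burst HFO packets."""
    kw = dict(group="lesion", n_swd=1, hfo_rate=0.5, seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


# ---------------------------------------------------------------------------
# noise


def _noise_shape(n: int, fs: float, exponent: float) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    return freqs, shape


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float,
                std: float, split_hz: float | None = None):
    """1/f^exponent Gaussian noise, optionally split into complementary
    low/high spectral parts (low + high == full, exactly)."""
    freqs, shape = _noise_shape(n, fs, exponent)
    spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    # E|a+jb|^2 = 2 and irfft doubles every positive-frequency bin, so the
    # expected variance of the output is 4 * sum(shape^2) / n^2 per unit scale
    norm = 2.0 * np.sqrt(np.sum(shape**2)) / n
    spec *= std / norm if norm > 0 else 1.0
    if split_hz is None:
        return np.fft.irfft(spec, n)
    low_mask = freqs < split_hz
    low = np.fft.irfft(np.where(low_mask, spec, 0), n)
    high = np.fft.irfft(np.where(low_mask, 0, spec), n)
    return low, high


def noise_band_sigma(config: SynthConfig, band: tuple[float, float]) -> float:
    """Expected SD of the background restricted to a frequency band.

    Exact for the generator's spectral-shaping construction (up to the
    sampling fluctuation of the white spectrum).
    """
    n = int(round(config.duration * config.fs))
    freqs, shape = _noise_shape(n, config.fs, config.noise_exponent)
    w2 = shape**2
    sel = (freqs >= band[0]) & (freqs < band[1])
    return config.noise_std * math.sqrt(w2[sel].sum() / w2.sum())


def packet_amplitude(amp_sd: float, sigma_band: float) -> float:
    """Carrier amplitude for a ripple packet labelled ``amp_sd``.

    Convention: the *measured* band envelope (packet plus noise, summed
    incoherently) peaks ``amp_sd`` robust SDs above the baseline
    envelope median.  This makes generator amplitude units commensurate
    with detector threshold units.
    """
    target = (RAYLEIGH_MEDIAN + amp_sd * RAYLEIGH_ROBUST_SD) * sigma_band
    floor = RAYLEIGH_MEDIAN * sigma_band
    return math.sqrt(max(target**2 - floor**2, 0.0))


# ---------------------------------------------------------------------------
# epochs


def _alternating_epochs(rng, config: SynthConfig):
    """Alternating suppression/burst epochs covering the recording."""
    if config.burst_rate <= 0:
        return [(0.0, config.duration)], []
    lo, hi = config.burst_dur
    mean_burst = 0.5 * (lo + hi)
    gap_mean = max(0.3, 1.0 / config.burst_rate - mean_burst)
    bursts, sups = [], []
    t = 0.0
    while t < config.duration:
        gap = gap_mean * rng.uniform(0.7, 1.3)
        s0, s1 = t, min(t + gap, config.duration)
        if s1 > s0:
            sups.append((s0, s1))
        t = s1
        if t >= config.duration:
            break
        bdur = rng.uniform(lo, hi)
        b0, b1 = t, min(t + bdur, config.duration)
        if b1 - b0 >= 0.1:
            bursts.append((b0, b1))
        t = b1
    return bursts, sups


def _merge_epochs(epochs):
    if not epochs:
        return []
    epochs = sorted(epochs)
    out = [list(epochs[0])]
    for s, e in epochs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _complement(epochs, duration):
    out, t = [], 0.0
    for s, e in epochs:
        if s > t:
            out.append((t, s))
        t = max(t, e)
    if t < duration:
        out.append((t, duration))
    return out


def _mask_from_epochs(epochs, n, fs):
    mask = np.zeros(n, dtype=bool)
    for s, e in epochs:
        mask[int(round(s * fs)): int(round(e * fs))] = True
    return mask


def _place_swds(rng, config: SynthConfig):
    """Non-overlapping SWD epochs, away from the recording edges."""
    epochs = []
    for _ in range(config.n_swd):
        for _attempt in range(200):
            start = rng.uniform(0.5, config.duration - config.swd_dur - 0.5)
            cand = (start, start + config.swd_dur)
            if all(cand[1] + 0.5 < s or cand[0] > e + 0.5 for s, e in epochs):
                epochs.append(cand)
                break
    return sorted(epochs)


# ---------------------------------------------------------------------------
# waveform templates


def spike_wave_template(fs: float, freq: float, amp: float) -> tuple[np.ndarray, int]:
    """One period of the spike-wave complex.

    A sharp biphasic transient (small positive pre-lobe, deep negative
    trough, total < 25 ms) followed by a slow positive after-wave
    (~60 ms).  Returns the template and the sample index of the trough.
    """
    period = 1.0 / freq
    n = int(round(period * fs))
    t = np.arange(n) / fs
    t_tr = 0.015
    w = -amp * np.exp(-((t - t_tr) ** 2) / (2 * 0.004**2))
    w += 0.25 * amp * np.exp(-((t - (t_tr - 0.010)) ** 2) / (2 * 0.003**2))
    wave0 = t_tr + 0.012
    in_wave = (t >= wave0) & (t < wave0 + 0.060)
    w[in_wave] += 0.45 * amp * np.sin(np.pi * (t[in_wave] - wave0) / 0.060)
    return w, int(round(t_tr * fs))


def spike_template(fs: float, trough_peak_ms: float, halfwidth_ms: float,
                   amplitude: float) -> tuple[np.ndarray, int]:
    """Extracellular spike waveform: negative trough of given
    half-amplitude width plus a positive after-peak at the given
    trough-to-peak latency.  Returns (template, trough index)."""
    dur_ms = max(3.0, trough_peak_ms + 3 * halfwidth_ms + 1.0)
    n = int(round(dur_ms * 1e-3 * fs))
    t = (np.arange(n) / fs) * 1e3  # ms
    t_tr = dur_ms * 0.35
    sig_tr = halfwidth_ms / 2.355
    w = -amplitude * np.exp(-((t - t_tr) ** 2) / (2 * sig_tr**2))
    sig_pk = 2.0 * sig_tr
    w += 0.35 * amplitude * np.exp(-((t - (t_tr + trough_peak_ms)) ** 2) / (2 * sig_pk**2))
    return w, int(round(t_tr * 1e-3 * fs))


def _gaussian_packets(n, fs, centers, sigma_s):
    """Sum of unit-peak Gaussian envelopes at the given centre times."""
    env = np.zeros(n)
    half = int(round(5 * sigma_s * fs))
    for c in centers:
        i = int(round(c * fs))
        lo, hi = max(0, i - half), min(n, i + half)
        if hi > lo:
            tt = (np.arange(lo, hi) - i) / fs
            np.maximum(env[lo:hi], np.exp(-(tt**2) / (2 * sigma_s**2)), out=env[lo:hi])
    return env


# ---------------------------------------------------------------------------
# spike trains


def make_spike_trains(config: SynthConfig, ripple_phase_deg: np.ndarray,
                      burst_mask: np.ndarray | None = None,
                      rng: np.random.Generator | None = None):
    """Draw spike trains for every unit spec against a ripple phase signal.

    Spikes come from an inhomogeneous Poisson process (``rate_burst``
    inside bursts, ``rate_suppression`` outside) thinned by a von Mises
    acceptance rule ``exp(kappa * (cos(phase - mu) - 1))`` on the
    instantaneous ripple phase; a 1 ms minimum inter-spike interval is
    enforced.  Returns (spike_times, true_phases, classes) keyed by unit
    index.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(ripple_phase_deg)
    fs = config.fs
    if burst_mask is None:
        burst_mask = np.ones(n, dtype=bool)
    times_out, phase_out, class_out = {}, {}, {}
    for uid, spec in enumerate(config.unit_specs):
        rate_max = max(spec.rate_burst, 1e-12)
        n_cand = rng.poisson(rate_max * n / fs)
        cand = np.sort(rng.uniform(0, n / fs, size=n_cand))
        idx = np.minimum((cand * fs).astype(int), n - 1)
        rate = np.where(burst_mask[idx], spec.rate_burst, spec.rate_suppression)
        phase = ripple_phase_deg[idx]
        accept_p = (rate / rate_max) * np.exp(
            spec.phase_kappa * (np.cos(np.radians(phase - spec.phase_mu)) - 1.0)
        )
        keep = rng.uniform(size=n_cand) < accept_p
        t_keep, ph_keep = cand[keep], phase[keep]
        # enforce 1 ms refractory period
        times, phases = [], []
        last = -np.inf
        for t_s, ph in zip(t_keep, ph_keep):
            if t_s - last >= 1e-3:
                times.append(t_s)
                phases.append(ph)
                last = t_s
        times_out[uid] = np.asarray(times)
        phase_out[uid] = np.asarray(phases) % 360.0
        class_out[uid] = spec.cell_class
    return times_out, phase_out, class_out


# ---------------------------------------------------------------------------
# main generator


def make_recording(config: SynthConfig, return_components: bool = False):
    """Generate a laminar recording and its ground-truth manifest.

    Returns ``(Recording, GroundTruth)``; with ``return_components=True``
    a third dict maps component name to its channels x samples array
    (components are generated independently, so their variances add).
    """
    rng = np.random.default_rng(config.seed)
    fs, n_ch = config.fs, config.n_channels
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    # --- epochs ------------------------------------------------------------
    burst_epochs, _ = _alternating_epochs(rng, config)
    swd_epochs = _place_swds(rng, config) if config.n_swd > 0 else []
    swd_spikes = []
    for s, e in swd_epochs:
        k = int(math.floor((e - s - 0.03) * config.swd_freq)) + 1
        swd_spikes.extend(s + 0.015 + np.arange(k) / config.swd_freq)
    swd_spikes = np.asarray(swd_spikes)

    burst_epochs = _merge_epochs(burst_epochs + list(swd_epochs))
    sup_epochs = _complement(burst_epochs, config.duration)
    burst_mask = _mask_from_epochs(burst_epochs, n, fs)
    smooth_samples = max(1, int(round(0.010 * fs)))
    burst_smooth = gaussian_filter1d(burst_mask.astype(float), smooth_samples)
    modulated = config.burst_rate > 0
    mod = config.suppression_floor + (1 - config.suppression_floor) * burst_smooth \
        if modulated else np.ones(n)

    # the laminar gain applies to LFP-range activity as well as ripples
    lfp_prof = config.ripple_amp_profile
    components = {}
    samples = np.zeros((n_ch, n))

    # --- background 1/f noise ----------------------------------------------
    background = np.empty((n_ch, n))
    for ch in range(n_ch):
        if modulated:
            low, high = _pink_noise(rng, n, fs, config.noise_exponent,
                                    config.noise_std, split_hz=100.0)
            background[ch] = low * mod + high
        else:
            background[ch] = _pink_noise(rng, n, fs, config.noise_exponent,
                                         config.noise_std)
    samples += background
    if return_components:
        components["background"] = background.copy()

    # --- shared burst LFP ---------------------------------------------------
    if modulated and config.burst_lfp_std > 0:
        freqs, shape = _noise_shape(n, fs, 0.0)
        sel = (freqs >= 1.0) & (freqs < 15.0)
        spec = np.where(
            sel,
            rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)),
            0.0,
        )
        norm = 2.0 * math.sqrt(float(sel.sum())) / n
        src = np.fft.irfft(spec * (config.burst_lfp_std / norm), n) * burst_smooth
        burst_lfp = lfp_prof[:, None] * src[None, :]
        samples += burst_lfp
        if return_components:
            components["burst_lfp"] = burst_lfp

    # --- spike-wave discharges ----------------------------------------------
    if len(swd_spikes):
        template, tr_idx = spike_wave_template(fs, config.swd_freq, config.swd_amp)
        train = np.zeros(n)
        for ts in swd_spikes:
            i0 = int(round(ts * fs)) - tr_idx
            lo, hi = max(0, i0), min(n, i0 + len(template))
            train[lo:hi] += template[lo - i0: hi - i0]
        swd_sig = lfp_prof[:, None] * train[None, :]
        samples += swd_sig
        if return_components:
            components["swd"] = swd_sig

    # --- ripples -------------------------------------------------------------
    sigma_band = noise_band_sigma(config, config.ripple_band)
    carrier = np.cos(2 * np.pi * config.ripple_freq * t)
    ripple_env = np.zeros(n)
    if len(swd_spikes):
        sig_w = config.swd_ripple_cycles / (2.355 * config.ripple_freq)
        packets = _gaussian_packets(n, fs, swd_spikes, sig_w)
        swd_mask = gaussian_filter1d(
            _mask_from_epochs(swd_epochs, n, fs).astype(float), smooth_samples
        )
        amp = packet_amplitude(config.swd_ripple_amp_sd, sigma_band)
        ripple_env += amp * swd_mask * ((1 - config.cfc_depth) + config.cfc_depth * packets)

    if config.burst_ripple_amp_sd > 0:
        amp = packet_amplitude(config.burst_ripple_amp_sd, sigma_band)
        ripple_env += amp * burst_smooth

    hfo_events = []
    if config.hfo_rate > 0:
        sig_w = config.hfo_cycles / (2.355 * config.ripple_freq)
        half_dur = 2.5 * sig_w
        amp = packet_amplitude(config.hfo_amp_sd, sigma_band)
        centers = []
        for s, e in burst_epochs:
            if any(s < se and e > ss for ss, se in swd_epochs):
                continue
            n_pk = rng.poisson(config.hfo_rate * (e - s))
            for c in np.sort(rng.uniform(s + half_dur, max(s + half_dur, e - half_dur),
                                         size=n_pk)):
                centers.append(float(c))
        centers = [c for i, c in enumerate(centers)
                   if i == 0 or c - centers[i - 1] > 4 * half_dur]
        if centers:
            ripple_env += amp * _gaussian_packets(n, fs, centers, sig_w)
        hfo_events = [(c - half_dur, c + half_dur) for c in centers]

    if np.any(ripple_env):
        ripple = config.ripple_amp_profile[:, None] * (ripple_env * carrier)[None, :]
        samples += ripple
        if return_components:
            components["ripple"] = ripple

    # --- line noise ----------------------------------------------------------
    if config.line_freq:
        line = config.line_amp * np.sin(2 * np.pi * config.line_freq * t)
        samples += line[None, :]
        if return_components:
            components["line"] = np.broadcast_to(line, (n_ch, n)).copy()

    # --- units ---------------------------------------------------------------
    ripple_phase = np.degrees(2 * np.pi * config.ripple_freq * t) % 360.0
    unit_times, unit_phase, unit_class = make_spike_trains(
        config, ripple_phase, burst_mask, rng
    )
    if config.unit_specs:
        spikes_sig = np.zeros((n_ch, n))
        for uid, spec in enumerate(config.unit_specs):
            tmpl, tr_idx = spike_template(
                fs, spec.trough_peak, spec.waveform_halfwidth, spec.amplitude
            )
            for ts in unit_times[uid]:
                i0 = int(round(ts * fs)) - tr_idx
                lo, hi = max(0, i0), min(n, i0 + len(tmpl))
                spikes_sig[spec.channel, lo:hi] += tmpl[lo - i0: hi - i0]
        samples += spikes_sig
        if return_components:
            components["units"] = spikes_sig

    rec = Recording(
        samples=samples,
        fs=fs,
        channel_depths=electrode_depths(n_ch),
        group=config.group,
        meta={"synthetic": True, "seed": config.seed},
    )
    if n_ch == 16:
        assign_laminae(rec)
    gt = GroundTruth(
        burst_epochs=burst_epochs,
        suppression_epochs=sup_epochs,
        swd_epochs=swd_epochs,
        hfo_events=hfo_events,
        swd_spike_times=swd_spikes,
        unit_spike_times=unit_times,
        unit_true_phase=unit_phase,
        unit_true_class=unit_class,
    )
    if return_components:
        return rec, gt, components
    return rec, gt


def write_ground_truth_csv(gt: GroundTruth, out_dir: str | Path) -> None:
    """Ground truth as CSV manifests: events.csv (kind,start_s,end_s) and
    spikes.csv (unit_id,time_s,phase_deg,cell_class)."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for kind, epochs in (
        ("burst", gt.burst_epochs),
        ("suppression", gt.suppression_epochs),
        ("SWD", gt.swd_epochs),
        ("hfo", gt.hfo_events),
    ):
        rows += [{"kind": kind, "start_s": s, "end_s": e} for s, e in epochs]
    pd.DataFrame(rows, columns=["kind", "start_s", "end_s"]).to_csv(
        out / "events.csv", index=False
    )
    srows = [
        {
            "unit_id": uid,
            "time_s": float(ts),
            "phase_deg": float(ph),
            "cell_class": gt.unit_true_class[uid],
        }
        for uid in gt.unit_spike_times
        for ts, ph in zip(gt.unit_spike_times[uid], gt.unit_true_phase[uid])
    ]
    pd.DataFrame(srows, columns=["unit_id", "time_s", "phase_deg", "cell_class"]).to_csv(
        out / "spikes.csv", index=False
    )
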