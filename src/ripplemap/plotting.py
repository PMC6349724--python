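"""Figure helpers: spectral heat maps, SFC curves, polar phase plots."""

from __future__ import annotations

import numpy as np


def _ax(ax, polar=False):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(subplot_kw={"projection": "polar"} if polar else None)
    return ax


def plot_spectral_map(spectral_map, ax=None, cmap="viridis", mask=None, **imshow_kw):
    """Frequency x channel heat map; optional significance contour mask."""
    ax = _ax(ax)
    extent = [
        spectral_map.channels[0] + 0.5,
        spectral_map.channels[-1] + 1.5,
        spectral_map.freqs[0],
        spectral_map.freqs[-1],
    ]
    im = ax.imshow(
        spectral_map.values, aspect="auto", origin="lower", extent=extent,
        cmap=cmap, **imshow_kw,
    )
    if mask is not None and mask.any():
        ax.contour(
            np.linspace(extent[0], extent[1], mask.shape[1]),
            spectral_map.freqs, mask.astype(float), levels=[0.5], colors="white",
        )
    ax.set_xlabel("channel")
    ax.set_ylabel("frequency (Hz)")
    return im


def plot_sfc(profile, ax=None, freq_range=None, **plot_kw):
    """SFC curve of one unit."""
    ax = _ax(ax)
    f, v = profile.freqs, profile.sfc
    if freq_range is not None:
        sel = (f >= freq_range[0]) & (f <= freq_range[1])
        f, v = f[sel], v[sel]
    ax.plot(f, v, **plot_kw)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("SFC")
    ax.set_ylim(0, 1)
    return ax


def plot_phase_polar(hist, ax=None, **bar_kw):
    """Polar firing-probability histogram with the mean direction marked."""
    ax = _ax(ax, polar=True)
    theta = np.radians(hist.bin_centers)
    width = np.radians(np.diff(hist.bin_edges))
    ax.bar(theta, hist.firing_probability, width=width, align="center", **bar_kw)
    if np.isfinite(hist.mean_angle):
        ax.annotate(
            "", xy=(np.radians(hist.mean_angle),
                    hist.resultant_length * hist.firing_probability.max()),
            xytext=(0, 0), arrowprops={"arrowstyle": "->", "color": "red"},
        )
    return ax
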