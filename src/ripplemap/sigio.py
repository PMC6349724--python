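"""Recording container and simple on-disk formats.

A :class:`Recording` is a channels x samples matrix in microvolts with a
sampling rate, per-channel vertical depths and laminar labels, and a
group label (control | lesion).  The native on-disk format is a flat
little-endian int16 payload plus a JSON sidecar carrying the scale
factor and all metadata; events and spikes travel as plain CSV.

The default geometry is a 16-channel linear array with 100 µm contact
spacing, inserted 40° from vertical, so the vertical (depth) spacing is
100·cos(40°) ≈ 76.6 µm and channel 1 sits at the cortical surface.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "electrode_depths",
    "assign_laminae",
    "read_recording",
    "write_recording",
    "write_events_csv",
    "read_events_csv",
    "write_spikes_csv",
    "read_spikes_csv",
]

LAMINA_LABELS = ("SG", "G", "IG", "subcortical")

#: channel-index (0-based) slices for the fixed 16-channel laminar map:
#: channels 1-3 supragranular, 4-6 granular, 7-12 infragranular, 13-16 subcortical
_LAMINA_SLICES = {"SG": (0, 3), "G": (3, 6), "IG": (6, 12), "subcortical": (12, 16)}


@dataclass
class Recording:
    """Multichannel extracellular recording, channels x samples, µV."""

    samples: np.ndarray
    fs: float
    channel_depths: np.ndarray | None = None
    lamina_labels: list[str] | None = None
    group: str = "control"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x samples array")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.channel_depths is None:
            self.channel_depths = electrode_depths(self.n_channels)
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        if len(self.channel_depths) != self.n_channels:
            raise ValueError("channel_depths length must match channel count")
        if np.any(np.diff(self.channel_depths) < 0):
            raise ValueError("channel depths must be non-decreasing with channel index")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def electrode_depths(
    n_channels: int = 16, spacing_um: float = 100.0, insertion_angle_deg: float = 40.0
) -> np.ndarray:
    """Vertical contact depths (µm) for a linear array inserted at an angle.

    Depth of channel *i* (0-based) = i · spacing · cos(angle); channel 1
    is taken as the cortical surface (0 µm).
    """
    step = spacing_um * math.cos(math.radians(insertion_angle_deg))
    return np.arange(n_channels) * step


def assign_laminae(rec: Recording) -> Recording:
    """Attach the fixed 16-channel laminar mapping to a recording.

    Channels 1–3 → SG, 4–6 → G, 7–12 → IG, 13–16 → subcortical
    (1-based channel numbering).  Non-16-channel recordings must carry
    explicit labels instead.
    """
    if rec.n_channels != 16:
        raise ValueError(
            "the fixed laminar map applies to 16-channel arrays only; "
            "supply lamina_labels explicitly for other geometries"
        )
    labels = [""] * 16
    for name, (lo, hi) in _LAMINA_SLICES.items():
        for i in range(lo, hi):
            labels[i] = name
    rec.lamina_labels = labels
    return rec


# ---------------------------------------------------------------------------
# native binary + JSON sidecar


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write int16 payload + JSON sidecar; write∘read is the identity.

    The scale factor maps the maximum absolute sample onto >= 90% of the
    int16 range, so quantisation noise is far below thermal noise.
    """
    path = Path(path)
    peak = float(np.max(np.abs(rec.samples))) if rec.samples.size else 0.0
    scale = (0.95 * 32767.0 / peak) if peak > 0 else 1.0
    payload = np.round(rec.samples * scale).astype("<i2")
    path.with_suffix(".bin").write_bytes(payload.tobytes())
    sidecar = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "scale": scale,
        "channel_depths_um": list(map(float, rec.channel_depths)),
        "lamina_labels": rec.lamina_labels,
        "group": rec.group,
        "meta": rec.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises if the sidecar is missing, inconsistent with the payload size,
    or carries an invalid sampling rate.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar {sidecar_path} not found")
    sc = json.loads(sidecar_path.read_text())
    if not sc.get("fs", 0) > 0:
        raise ValueError(f"sidecar fs must be positive, got {sc.get('fs')}")
    raw = np.frombuffer(path.with_suffix(".bin").read_bytes(), dtype="<i2")
    expected = sc["n_channels"] * sc["n_samples"]
    if raw.size != expected:
        raise ValueError(
            f"payload has {raw.size} samples but sidecar declares "
            f"{sc['n_channels']} x {sc['n_samples']} = {expected}"
        )
    samples = raw.reshape(sc["n_channels"], sc["n_samples"]).astype(float) / sc["scale"]
    return Recording(
        samples=samples,
        fs=sc["fs"],
        channel_depths=np.asarray(sc["channel_depths_um"]),
        lamina_labels=sc["lamina_labels"],
        group=sc.get("group", "control"),
        meta=sc.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# CSV interchange for events and spikes


def write_events_csv(events, path: str | Path) -> None:
    """Events as CSV with columns kind, channel, start_s, end_s."""
    rows = [
        {
            "kind": getattr(e, "kind", getattr(e, "band_name", "event")),
            "channel": getattr(e, "channel", -1),
            "start_s": e.start,
            "end_s": e.end,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["kind", "channel", "start_s", "end_s"]).to_csv(
        path, index=False
    )


def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spikes_csv(spike_times_by_unit: dict, path: str | Path) -> None:
    """Spike times as CSV with columns unit_id, time_s (one row per spike)."""
    rows = [
        {"unit_id": uid, "time_s": float(t)}
        for uid, times in spike_times_by_unit.items()
        for t in np.atleast_1d(times)
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def read_spikes_csv(path: str | Path) -> dict:
    df = pd.read_csv(path)
    return {uid: g["time_s"].to_numpy() for uid, g in df.groupby("unit_id")}
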