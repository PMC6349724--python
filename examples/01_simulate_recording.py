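"""Generate a synthetic laminar recording and inspect its ground truth.

Builds a 15 s, 16-channel "lesion-like" recording at 20 kHz: anesthesia
burst-suppression, one 11 Hz spike-wave discharge whose spike troughs
carry 300–800 Hz ripple packets, discrete burst HFOs, and a laminar
amplitude gradient strongest superficially.
"""

import numpy as np

from ripplemap import make_recording, write_recording
from ripplemap.synth import lesion_config, write_ground_truth_csv

cfg = lesion_config(seed=42, duration=15.0)
rec, gt = make_recording(cfg)

print(f"recording: {rec.n_channels} channels x {rec.duration:.0f} s at {rec.fs:.0f} Hz")
print(f"laminar labels: {rec.lamina_labels}")
print(f"burst epochs: {[(round(s,2), round(e,2)) for s, e in gt.burst_epochs]}")
print(f"SWD epochs:   {[(round(s,2), round(e,2)) for s, e in gt.swd_epochs]}")
print(f"SWD spike deflections: {len(gt.swd_spike_times)} "
      f"(≈ {cfg.swd_freq:.0f}/s during the discharge)")
print(f"burst HFO packets: {len(gt.hfo_events)}")
print(f"channel RMS (µV), superficial→deep gradient: "
      f"{np.round(rec.samples.std(axis=1), 1)}")

write_recording(rec, "scratch_example_recording")
write_ground_truth_csv(gt, "scratch_example_ground_truth")
print("wrote scratch_example_recording.{bin,json} and "
      "scratch_example_ground_truth/{events,spikes}.csv")
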