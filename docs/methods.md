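# Methods

`ripplemap` analyses laminar extracellular recordings of epileptiform
activity: high-frequency oscillations (HFOs), spike-wave discharges
(SWDs), anesthesia-induced burst-suppression (B-S), laminar spectral
maps, extracellular unit classification, and spike–field coupling.  It
ships a synthetic-data generator with exhaustive ground truth so every
stage can be validated end to end.  This note records the models, the
defaults and why, the numerical choices, and what the synthetic tests
do and do not establish about real data.

## Band scheme and filtering

Five canonical bands: low (1–25 Hz), gamma (25–100 Hz), low-frequency
ripple (LFR, 100–300 Hz), high-frequency ripple (HFR, 300–800 Hz) and
multi-unit activity (MUA, 800–5000 Hz).  The low band's lower edge
(1 Hz) follows the usual acquisition band-pass.  Filtering uses an
odd-length symmetric Hamming-window FIR applied once, centred, via FFT
overlap-add: a linear-phase kernel applied this way has exactly zero
net group delay, which a forward–backward IIR only approximates in its
pass-band.  Kernel length is ~3 cycles of the band's low edge, capped
at 8192 taps; edges are reflect-padded by one kernel length.
Consequences worth knowing: stop-band attenuation is ~53 dB
(single-pass Hamming); the low band's 1 Hz edge cannot be sharp at
20 kHz under the tap cap; a long kernel smears sharp periodic
structure outward by up to half its length, which is why the SWD
detector does its trough work on a short (half-cycle) kernel.

Two MUA conventions coexist in the field (300–3000 Hz for spike
extraction, 800–5000 Hz as an analysis band).  `canonical_bands()`
uses 800–5000; spike detection defaults to 300–3000 but the examples
detect in 800–5000 when strong ripples would otherwise contaminate the
detection band, then extract classification waveforms from 300–3000
(`snippets_at`).

## Synthetic recordings

The generator is phenomenological.  A recording is a sum of
independently generated components:

- **1/f background** (default exponent 1.0, total SD 15 µV), built by
  spectral shaping of white Gaussian noise, flattened below 1 Hz.
  Burst-suppression modulates only the <100 Hz share of this noise
  (suppression floor 0.15): physiologically, suppression silences
  synaptic currents while the wide-band noise floor is stationary.
  Practically, this keeps the suppression-epoch ripple-band baseline
  representative of in-burst background, which is what an HFO detector
  baselines against.
- **Burst epochs**: alternating suppression/burst, burst durations
  uniform on 0.5–2 s, cycle rate 0.25 /s, plus a shared 1–15 Hz burst
  LFP source (40 µV) scaled by the laminar profile.
- **SWD**: a spike-wave template train at 10–12 Hz (default 11 Hz) for
  ≥1 s (default 2 s): a biphasic sharp transient (<25 ms; small
  positive pre-lobe, deep trough) plus a 60 ms half-sine after-wave,
  trough depth 300 µV.  The template shape and its amplitude relative
  to baseline are free parameters — published figures show but do not
  parameterise them.
- **Ripples**: a coherent carrier at 500 Hz (inside the 300–800 Hz
  band) with a Gaussian envelope per packet.  Packet width is given as
  the FWHM of the envelope in carrier cycles (default 8, within the
  plausible 4–12 range).  During SWDs the ripple envelope is
  `(1−cfc) + cfc · Σ packets at spike troughs`, so `cfc_depth` ∈ [0, 1]
  is a true modulation index: 0 gives a phase-flat envelope, 1 gives
  packets fully locked to the spike troughs.  Discrete packets also
  occur inside bursts at `hfo_rate`; an optional continuous in-burst
  ripple supports phase-locking analyses.
- **Laminar gradient**: linear gain falloff 1.0 → 0.3 across the 12
  cortical channels, 0.15 subcortically (strongest superficial).
- **Units**: inhomogeneous Poisson spike trains (`rate_burst` inside
  bursts, `rate_suppression` outside), thinned by a von Mises
  acceptance rule `exp(κ(cos(θ−µ)−1))` on the instantaneous ripple
  phase, minimum ISI 1 ms.  Waveforms are a negative Gaussian trough
  (half-width `b`) plus a positive after-peak at latency `a`:
  EXC defaults a = 0.7 ms / b = 0.4 ms, INH a = 0.3 ms / b = 0.15 ms —
  canonical broad- vs narrow-spiking shapes on opposite sides of the
  classifier boundary.

**Amplitude convention.** Packet amplitudes are specified in multiples
of the robust SD of the baseline ripple-band envelope, *as a detector
measures it*: an `amp_sd = 4` packet is one whose measured envelope
peak (packet plus Rayleigh-distributed noise, summed incoherently) is
expected to sit 4 robust SDs above the baseline envelope median.  The
band SD is computed analytically from the spectral shaping, so the
label is exact up to the ~5–10 % loss at the band-pass transition
edges (labelled packets are slightly conservative).

What the generator does **not** emulate: electrode drift, movement and
EMG artifacts, non-stationary background spectra, spike waveform
variability and bursting, volume-conducted far-field events,
physiological (non-pathological) HFOs, and spatially propagating
discharges.  Passing tests establish correctness of the analysis
algebra and detector calibration under the stated noise model — not
detector performance on real tissue.

## Burst-suppression segmentation

Envelope of the 1–100 Hz band, smoothed 50 ms; the threshold is the
midpoint (in log amplitude) of the two modes found by 1-D 2-means,
with 20 % hysteresis; minimum burst 100 ms, minimum suppression
200 ms.  A unimodal envelope (mode separation < 0.2 decades) makes the
whole recording one epoch — burst if the median envelope exceeds
30 µV, suppression otherwise; that absolute floor is the one scale the
data cannot supply.  Flat signals return a single suppression epoch
with a warning.

## SWD detection

Candidates are regions where the (9–13 Hz)/(1–50 Hz) smoothed-power
ratio exceeds 0.4 (0.1 s Gaussian smoothing), merged across <200 ms
gaps, pruned to ≥1 s.  Within a candidate, spike troughs are found on a
short-kernel 5–45 Hz trace (half a cycle of the low edge — a long
zero-phase kernel would smear the periodic train outward by its own
length); the discharge is the longest run of troughs at 10–12 Hz
spacing ±20 %, where a single missed trough may bridge a run as a
double-period gap, shallow (<50 % median depth) edge deflections are
trimmed, and ≥8 regular troughs are required.  Epoch boundaries are
the first/last trough ± half a period — sharper than the smeared power
ratio.  On synthetic data this places boundaries within ~30 ms (clean)
to ~100 ms (full noise model) of truth.

## HFO detection

Per channel and band: band-pass, Hilbert envelope, and band power
smoothed with a Gaussian of FWHM 8 cycles of the band centre — a
near-matched filter for the canonical packet width.  Baseline median
and robust SD (MAD/0.6745, resistant to event contamination) come from
suppression epochs when a segmentation is supplied, else from the
quietest-quartile envelope windows.  A candidate is a region of
smoothed power above median + 1.5·SD whose peak exceeds median + 3·SD;
it must contain ≥4 oscillation peaks above half its own peak envelope
(an amplitude-invariant cycle count: a strong but brief transient
cannot buy duration with amplitude); it is confirmed when its peak
smoothed in-band power exceeds the baseline mean power by ≥6 dB (the
spectrographic check).  With a segmentation supplied, events outside
bursts are discarded.  On the synthetic null this operating point
yields ≈0 false positives per burst-minute while recovering ≥90 % of
≥4 SD packets of the canonical width; the 4 SD / 4-cycle corner is
intrinsically marginal against 1/f in-band noise and sensitivity there
is dominated by destructive packet–noise interference, not by the
thresholds.

## Spectral mapping

Welch PSD with 0.5 s Hann windows, 50 % overlap (2 Hz resolution on
2–5 s segments), reported as 10·log₁₀(µV²/Hz); the dB reference is
arbitrary, so only differences and masks are comparable.  Laminar maps
average per-recording dB over analysis segments; groups are compared
per (frequency, channel) cell with two-sample t-tests on dB,
Holm-Sidak corrected over the whole map.  Per-cell tests plus
step-down correction are the reproducible surface here; an omnibus
multifactorial ANOVA adds nothing to the masked difference map and is
not re-implemented.  Coherence is magnitude-squared coherence against
channel 1 (the most superficial contact), requiring ≥4 Welch windows
since one window gives identically 1; the independent-channel bias
floor is ~1/n_windows.  Perievent spectrograms use 25 ms windows at
5 ms steps (resolving 300–800 Hz with usable time resolution), aligned
and averaged over events; each time bin is compared against the t = 0
bin with paired t-tests, Holm-Sidak corrected, with edge events
dropped under warning.

## Units

Detection: negative crossings of the MUA band at 2 robust SDs
(configurable; the permissive contract value admits noise crossings by
design), trough-aligned 2 ms snippets, 1 ms dead time.  Sorting:
a running template-matching pass by waveform correlation gives the
initial grouping; the final partition is a Gaussian mixture on the
first 3 principal components with k ∈ {1..5} chosen by silhouette
(k = 1 unless some split reaches 0.45 — overlapping clusters merge
rather than split).  Clusters below the minimum size (10) are dropped;
with `min_amplitude_sd` set, clusters whose mean trough is shallower
than that many noise SDs (estimated from snippet edges) are discarded
as threshold noise and the remainder re-sorted once — the
"well-isolated" criterion replacing manual verification.  Clusters
with >1 % sub-millisecond ISIs are flagged.

Features on the mean waveform: a = trough-to-peak latency (ms),
b = trough half-amplitude width (ms, sub-sample interpolated),
c = peak/trough ratio.  Classification is linear in (a, b):
INH iff a < 0.55 − 0.5·b, ties to EXC (conservative for
inhibitory-phase-locking claims); no post-trough positive peak leaves
a unit unclassified.  The boundary is a field-standard
narrow/broad-spiking separator, exposed as parameters.  Waveform-based
classification is known to misclassify up to ~30 % of inhibitory
cells; nothing here corrects for that, and downstream group contrasts
inherit it.

## Phase and spike–field coupling

Phase convention: analytic-signal angle with 0° at the positive peak,
90° at the falling zero-crossing, 180° at the trough.  Published polar
plots sometimes use another origin; `origin_deg` shifts reported
phases and every output records the convention.  Zero-phase (cycle
reference) timestamps are upward crossings of phase 0, linearly
interpolated, counted only where the envelope — smoothed over ~4
cycles of the dominant frequency to de-spike the Rayleigh tail —
exceeds twice its median (capped at half the maximum so constant
envelopes remain countable).  Spike phases interpolate the analytic
signal at spike times.  Circular statistics (mean direction, resultant
length, Rayleigh test with Zar's finite-n correction) are implemented
directly and cross-checked against an independent implementation in
the tests.

A caveat the examples demonstrate: a spike waveform leaks into the
ripple band of its own electrode, biasing same-channel spike-phase
estimates toward the artifact's phase; detecting spikes in 800–5000 Hz
and measuring phase on a neighbouring channel are the standard guards.

SFC uses the spike-triggered-average estimator: the power spectrum of
the STA divided by the mean power spectrum of the individual
spike-centred segments (±100 ms, Hann-tapered — long enough for ~10 Hz
resolution while holding ≥40 ripple cycles).  It is bounded in [0, 1],
reaches 1 in the perfect-locking limit, is invariant to LFP gain, and
has a bias floor ≈ 1/n_spikes for unlocked spikes (so profiles from
units with very different spike counts are not directly comparable at
small SFC).  ≥50 spikes with full windows are required.  Depth
dependence is summarised by Pearson correlation between per-unit
maximum SFC and contact depth.  Group phase histograms (18 bins of
20°) are contrasted per bin with two-sample t-tests, Holm-Sidak
corrected, reporting the contiguous significant phase intervals.

## Inference

`fisher_exact` computes the two-sided p by the probability-ordering
rule with exact integer hypergeometric weights, so ties are resolved
exactly rather than to floating-point tolerance; the odds ratio is the
sample odds ratio with inf/nan on zero margins.  `holm_sidak` is the
step-down Sidak procedure; rejections always form a prefix of the
sorted p-values and lowering α never adds rejections.  Both are
verified against independent oracles (rational enumeration and scipy;
statsmodels) and by a 1000-repeat family-wise-error simulation.

## Geometry

The 16-contact linear array has 100 µm along-shank spacing and is
inserted 40° from vertical, so vertical depth = index × 100 × cos 40°
≈ 76.6 µm per contact, with channel 1 at the cortical surface (its
absolute depth relative to the pia is not otherwise constrained).
Laminar labels are fixed for the 16-channel geometry: channels 1–3
supragranular, 4–6 granular, 7–12 infragranular, 13–16 subcortical;
other geometries must supply labels explicitly.

## Problem sizes and determinism

Default synthetic recordings are 30 s of 16 channels at 20 kHz; the
cohort analysis uses 12 control and 20 lesion recordings; detector
calibration uses 30 s single-channel nulls and ≈90 labelled packets;
phase-null calibration uses 200 repeats; the Fisher oracle sweep
covers every 2×2 table with margins ≤ 40 (~130 000 distinct
conditional configurations after symmetry reduction).  Test fixtures
are shorter (10–20 s) where the property under test allows.  All
randomness flows from explicit integer seeds through
`numpy.random.Generator`; equal seeds give bit-identical recordings,
spike trains and pipeline CSVs.

## Known limitations

- Detector thresholds are calibrated on the generator's noise model;
  real recordings need re-calibration (all thresholds are exposed).
- The total-variance decomposition of a recording holds to ~5 % only
  for components without strong in-band overlap; the SWD train and the
  burst LFP share the ~10 Hz band, and their single-realisation
  covariance can be larger.
- Sorting is single-channel; no drift correction, no polytrode
  templates, no overlap resolution.
- The 1 Hz edge of the low band is soft at high sampling rates (tap
  cap); absolute PSD offsets are arbitrary by construction.
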