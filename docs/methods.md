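# Methods

This note documents the models and procedures implemented in `lfpipe`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Signal model and preprocessing

Recordings are multichannel voltage time-series in µV with a sampling rate,
per-channel region tags (CA1, NCX, DG) and named event markers (typically
`injection`). The native container is a little-endian float32 matrix plus a
JSON sidecar; EDF/EDF+ import is supported through `mne`, honoring the
file's physical dimensions. Proprietary acquisition formats (Spike2 `.smr`,
Neuralynx `.ncs`) are out of scope.

Analysis runs at 1000 Hz. Downsampling applies a zero-phase Kaiser-window
FIR low-pass with cutoff 0.45 × target rate (≥ 60 dB stopband per pass;
`filtfilt` doubles it) before decimation, preserving amplitude within 1 %
below 0.4 × target rate. An optional digital 1 Hz high-pass is available but
off by default, since hardware acquisition filtering is typically already
band-limited.

## Spectral estimation

**Spectrogram.** Sliding-window multitaper PSD: default 30 s windows
advanced in 3 s steps, labeled by window centers, yielding
`floor((T − 30)/3) + 1` bins. Each window is tapered with DPSS sequences;
defaults are time-bandwidth product NW = 3 with 5 tapers (a standard
multitaper default), giving ±0.1 Hz spectral concentration at 30 s windows.
Power is the mean one-sided density over tapers, stored linear (µV²/Hz);
decibel scaling is a display concern, and where a dB readout is wanted it is
10·log10 of a power ratio.

**Welch PSD.** 4 s Hann segments with 50 % overlap (configurable), no
detrending. The integral of the one-sided density over frequency
approximates the signal variance (Parseval), which the tests enforce within
5 % on stationary signals.

**Band power.** The density is treated as piecewise linear in frequency and
integrated over `[f_lo, f_hi]` with the band edges interpolated onto the
grid, so band power is exactly additive over any partition of a band. Named
bands follow the conventions of hippocampal/neocortical work: theta 4–12 Hz
(central theta 5–8), delta 1–4, slow delta 1–2, supratheta 10–20, CA1 gamma
30–140, ECoG gamma 30–60 (surface electrodes do not resolve higher), ripple
120–250.

**Baseline normalization.** Band-power series are divided by their mean
over a reference interval — by convention the first 5 min after injection —
so the baseline mean of the output is 1.

**Spectral entropy.** Per time bin, power across frequency is normalized to
sum 1 and the Shannon entropy is divided by ln(N bins): 1 for a flat
spectrum, 0 for a single-bin spectrum, invariant to scaling the spectrum by
any positive constant. All-zero bins map to 0 by definition. SpE measures
spectral complexity independent of signal amplitude, which makes it robust
to electrode-impedance and gain differences.

## Sharp-wave-ripple detection

The raw CA1 trace is band-pass filtered to 120–250 Hz with a zero-phase
Kaiser FIR (cutoffs half a transition width outside the band; passband flat
within 1 dB, stopband ≥ 40 dB an octave outside). The envelope is the
magnitude of the analytic (Hilbert-transformed) signal; its mean and SD are
computed over the entire analyzed epoch, not per scan window — per-window
statistics would make a 7 SD criterion unstable on 300 ms of data, and the
window scan is treated purely as a search procedure. This choice is pinned
by a test holding the windowed-scan detector equivalent to a brute-force
sample-wise implementation of the same rules.

Detection: any envelope sample above mean + 7 SD found while scanning
300 ms windows in 50 ms steps starts a candidate; the candidate is accepted
only if the envelope stays above mean + 3 SD for 10 ms after the crossing
(rejects single-sample artifacts). Event extent is the surrounding interval
above the 3 SD level; events separated by less than 30 ms are merged.
Peak-to-peak amplitude is measured on the ripple-band trace within the
event (the raw-trace variant is also computed but not the default, since
detection operates on the filtered trace). A recording is summarized by the
median peak-to-peak amplitude and the event rate over the sampling period.
The first and last 0.5 s are excluded from detection to avoid filter and
Hilbert edge artifacts. A constant trace (zero SD) yields an empty event
list with a warning.

## Cortical-mode segmentation and switch detection

Four modes are distinguished, following the standard rodent repertoire plus
the inflammation-induced state:

| mode | behavior | spectral signature |
|------|----------|--------------------|
| I | awake, mobile | theta 4–12 Hz peak + gamma |
| II | slow-wave sleep | 1–4 Hz dominance, up–down alternation |
| III | REM | theta without motion |
| IV | inflammation-like | broadband attenuation vs. II, ~3 Hz enhancement |

Labels are assigned per spectrogram bin by explicit rules: theta dominance
is (5–8 Hz power)/(1–4 Hz power) > 1.5; mobility is binned speed above
25 px/s (≈ 1 px/frame at 25 fps; configurable in calibrated units); mode IV
requires total broadband power below 0.6 × a slow-wave reference median.
Because mode IV is defined *relative to* slow-wave sleep, the reference is
taken from a designated baseline epoch (the pipeline uses the baseline
window's median broadband power); absent a reference, it is self-calibrated
as the median broadband power over immobile non-theta bins. Labels are
smoothed with a 5-bin majority filter, which suppresses single-bin flicker
without hiding bouts ≥ 15 s. Without a motion channel the I/III distinction
is impossible and theta bins are labeled `theta-state`. All rules use power
ratios and relative powers, so uniformly rescaling a recording does not
change labels once the reference is recomputed.

The thresholds are design choices that separate the generator's default
modes with margin; they are not a reconstruction of any manual scoring
procedure, and on real data they should be checked against video or EMG
where available.

**Switch detection.** On a baseline-normalized band-power series (gamma by
default), the switch is the earliest bin after the baseline window where
power stays below (1 − drop_frac) for a sustained run; defaults
drop_frac = 0.3 and 10 bins (30 s), robust to single-bin noise while far
finer than coarse visual timing. The detector reports the first *sustained
attenuation* — applied to a recording that contains natural sleep before
the event of interest it will flag sleep onset, so the search region and
baseline must be chosen accordingly (post-injection recordings in the
intended use). Group-level timing uses pointwise two-sided unpaired t-tests
(Welch by default) between groups of per-animal series, reported without
multiplicity correction and flagged as such.

## Motion

Pose input is the DeepLabCut CSV dialect (3-row header scorer / bodyparts /
coords; x, y, likelihood per bodypart). Frames below a likelihood cutoff
(default 0.9; well-trained networks report ~1 for > 99 % of frames) are
dropped and linearly interpolated. Traveled distance is the cumulative sum
of frame-to-frame Euclidean steps — rotation- and translation-invariant and
linear in a px→cm scale, reported in px unless a scale is configured. No
positional smoothing is applied by default; an optional 3-frame median
filter is available. The video frame rate is required metadata.

## Statistics

Unpaired two-sided t-tests (Welch default, pooled available — group sizes
are rarely equal in practice), Holm–Šidák step-down adjustment
(adjusted_i = 1 − (1 − p_i)^(m − i + 1) over ascending p with monotonicity
enforcement), and two-sided Fisher's exact tests. These delegate to
scipy/statsmodels and are verified in tests against independent oracles:
closed-form hand computation, full hypergeometric enumeration for every 2×2
table with margins ≤ 10, and a 10,000-replicate null simulation for the
t-test's type-I error. Degenerate zero-variance inputs are handled
explicitly (p = 1 for equal means, p → 0 with a warning otherwise). ANOVA
with post-hoc families is deliberately left to standard statistical
packages.

## Synthetic generator

The generator produces what the analysis assumes, with ground truth:

* **Background**: Gaussian noise spectrally shaped in the FFT domain to
  power ∝ 1/f^α, α = 1.5 by default (a plausible LFP slope), RMS set by
  `noise_scale` (50 µV) × the mode's `broadband_gain`.
* **Oscillators**: narrowband Gaussian noise with a Gaussian spectral
  profile (center, bandwidth, amplitude relative to background RMS). Default
  modes: I = 6 Hz theta (2.5×) + 40–80 Hz gamma (0.8×), mobile; II = 1.5 Hz
  slow oscillation (3.5×) with 0.75 Hz square-wave up–down amplitude
  modulation of the background; III = theta without motion; IV =
  broadband_gain 0.45 with 3 Hz (1.2×) and 6 Hz (0.5×) components. Mode IV's
  ~3 Hz amplitude is a free parameter read qualitatively from the state's
  description, not a calibrated value.
* **Transitions** are instantaneous at schedule boundaries, making
  switch-time ground truth unambiguous; the first entry into mode IV is the
  recorded switch time.
* **Ripples**: Poisson event times, Gaussian-windowed sinusoidal bursts
  (default 160 Hz, 50 ms mean duration) riding on a slower negative
  deflection standing in for the sharp wave (its exact shape is cosmetic for
  detector testing). The shared burst amplitude is calibrated by fixed-point
  iteration so event envelope peaks land `amplitude_snr` SDs above the mean
  of the injected trace's own ripple-band envelope — the same statistics a
  threshold detector computes over the epoch. Default SNR 10; at an SNR
  equal to the detection threshold + 1 the margin is a single envelope-noise
  SD and recall is intrinsically marginal, which is a property of
  threshold detection, not of any implementation. Overlapping ground-truth
  intervals are merged.
* **Trajectories**: reflected Gaussian random walk (3 px/frame/axis) during
  mobile modes, sub-pixel jitter otherwise; likelihood near 1 with rare
  exponential dips.

What the generator does **not** emulate: electrode drift and artifacts,
volume conduction between channels, continuous state transitions, theta
harmonics, phase-amplitude coupling, ripple-frequency variability within an
event, or any physiological coupling between motion and LFP beyond the mode
schedule. Passing tests therefore demonstrate correctness of the *analysis
operations* under the stated statistical structure, not performance on real
recordings.

## Problem sizes and determinism

Validation uses 10-minute traces for detector performance (10 seeds),
30 s traces for detector-oracle equivalence (50 seeds), 15-minute two-epoch
recordings for switch recovery (20 seeds), and 10-minute four-mode
schedules for segmentation (10 seeds); these sizes give stable estimates of
the tested properties at desk scale. All random streams derive from
`numpy` `default_rng` with explicit seed keys, so every result in the test
suite and the acceptance script is exactly reproducible; identical
simulation config and seed produce bit-identical recordings, and the demo
pipeline's output bundle is byte-identical across reruns.

## Known limitations

* Mode classification is rule-based with fixed thresholds; it does not
  learn from data and has no notion of intermediate or mixed states
  (`unknown` covers only zero-power bins).
* The switch detector assumes a clean baseline followed by attenuation; it
  will flag any sustained band-power drop, including sleep onset.
* Ripple amplitude statistics are measured on the band-passed trace;
  absolute µV values depend on the filter and are not comparable across
  different band definitions.
* EDF export is not implemented (import only).
* Pointwise p-value traces are intentionally uncorrected and should be read
  as descriptive, not confirmatory.
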