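"""Spectral estimation: multitaper spectrograms, Welch spectra, band power,
baseline normalization, and spectral entropy.

Defaults follow the analysis conventions for long LFP/ECoG follow-ups: 30 s
spectrogram windows advanced in 3 s steps (bins labeled by window centers),
time-bandwidth product 3 with 5 DPSS tapers, and 4 s Hann segments with 50 %
overlap for Welch spectra. All stored power is linear (µV²/Hz); dB is a
display concern. Band-limited ratios are reported as 10·log10 where a dB
readout is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recio import BandDef

__all__ = [
    "Spectrogram",
    "PowerSpectrum",
    "BandPowerSeries",
    "SpectralEntropyTrace",
    "multitaper_spectrogram",
    "welch_psd",
    "band_power",
    "normalize_power",
    "spectral_entropy",
]


@dataclass
class Spectrogram:
    times: np.ndarray      # s, window centers
    freqs: np.ndarray      # Hz
    power: np.ndarray      # (n_times, n_freqs), µV²/Hz
    params: dict = field(default_factory=dict)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray      # µV²/Hz, one-sided density
    params: dict = field(default_factory=dict)


@dataclass
class BandPowerSeries:
    times: np.ndarray
    values: np.ndarray     # µV² (band-integrated), unitless once normalized
    band: BandDef
    normalization: str | None = None


@dataclass
class SpectralEntropyTrace:
    times: np.ndarray
    values: np.ndarray     # in [0, 1]


def multitaper_spectrogram(signal: np.ndarray, fs: float, *,
                           window_s: float = 30.0, step_s: float = 3.0,
                           band: BandDef | tuple[float, float] = (1.0, 140.0),
                           nw: float = 3.0, n_tapers: int = 5) -> Spectrogram:
    """Multitaper PSD in sliding windows.

    Each window is tapered with ``n_tapers`` DPSS sequences of time-bandwidth
    product ``nw``; per-window power is the mean one-sided density over
    tapers. The number of time bins is floor((duration − window)/step) + 1 and
    bins are labeled by their window centers.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if step_s <= 0:
        raise ValueError("step_s must be > 0")
    n = signal.size
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if win > n:
        raise ValueError(f"window ({window_s} s) longer than signal ({n / fs} s)")
    if isinstance(band, BandDef):
        f_lo, f_hi = band.f_lo, band.f_hi
    else:
        f_lo, f_hi = band

    n_bins = (n - win) // step + 1
    starts = np.arange(n_bins) * step
    windows = np.lib.stride_tricks.sliding_window_view(signal, win)[::step][:n_bins]

    tapers = sps.windows.dpss(win, nw, Kmax=n_tapers)  # unit-energy rows
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    fmask = (freqs >= f_lo) & (freqs <= f_hi)
    power = np.zeros((n_bins, int(fmask.sum())))
    for taper in tapers:
        spec = np.fft.rfft(windows * taper, axis=1)[:, fmask]
        power += (spec.real ** 2 + spec.imag ** 2)
    power *= 2.0 / (fs * n_tapers)  # one-sided density; sum(taper²)=1
    times = (starts + win / 2.0) / fs
    return Spectrogram(times=times, freqs=freqs[fmask], power=power,
                       params={"window_s": window_s, "step_s": step_s,
                               "nw": nw, "n_tapers": n_tapers,
                               "band": (f_lo, f_hi), "fs": fs})


def welch_psd(signal: np.ndarray, fs: float, *, segment_s: float = 4.0,
              overlap_frac: float = 0.5) -> PowerSpectrum:
    """One-sided Welch power spectral density (Hann segments)."""
    signal = np.asarray(signal, dtype=np.float64)
    nperseg = int(round(segment_s * fs))
    if nperseg > signal.size:
        raise ValueError(f"segment ({segment_s} s) longer than signal")
    freqs, pxx = sps.welch(signal, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=int(round(overlap_frac * nperseg)),
                           detrend=False)
    return PowerSpectrum(freqs=freqs, power=pxx,
                         params={"segment_s": segment_s,
                                 "overlap_frac": overlap_frac, "fs": fs})


def _band_integral(freqs: np.ndarray, power: np.ndarray,
                   f_lo: float, f_hi: float) -> np.ndarray:
    """Integral of the piecewise-linear density over [f_lo, f_hi].

    Band edges are interpolated onto the frequency grid so that integrals are
    exactly additive over a partition of a band.
    """
    grid = freqs[(freqs > f_lo) & (freqs < f_hi)]
    pts = np.concatenate([[f_lo], grid, [f_hi]])
    vals = np.array([np.interp(pts, freqs, row) for row in np.atleast_2d(power)])
    out = np.trapezoid(vals, pts, axis=1)
    return out


def band_power(spec: Spectrogram | PowerSpectrum,
               band: BandDef) -> BandPowerSeries | float:
    """Trapezoidal band-integrated power; a series for spectrograms, a scalar
    for a single spectrum."""
    if band.f_lo < spec.freqs[0] or band.f_hi > spec.freqs[-1]:
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz outside spectrum "
            f"range [{spec.freqs[0]}, {spec.freqs[-1]}] Hz")
    vals = _band_integral(spec.freqs, spec.power, band.f_lo, band.f_hi)
    if isinstance(spec, PowerSpectrum):
        return float(vals[0])
    return BandPowerSeries(times=spec.times.copy(), values=vals, band=band)


def normalize_power(series: BandPowerSeries,
                    baseline: tuple[float, float]) -> BandPowerSeries:
    """Divide by the mean over the baseline interval (e.g. the first 5 min
    after injection); the output's baseline mean is 1."""
    t0, t1 = baseline
    mask = (series.times >= t0) & (series.times <= t1)
    if not mask.any():
        raise ValueError(f"baseline [{t0}, {t1}] s does not overlap series times")
    ref = float(series.values[mask].mean())
    if ref == 0:
        raise ValueError("baseline mean power is zero")
    return BandPowerSeries(times=series.times.copy(),
                           values=series.values / ref, band=series.band,
                           normalization=f"baseline_mean[{t0},{t1}]s")


def spectral_entropy(spec: Spectrogram) -> SpectralEntropyTrace:
    """Normalized Shannon entropy of each time bin's power distribution.

    Per bin, power is normalized to sum 1 and the entropy is divided by
    ln(n_freq_bins), giving values in [0, 1]: 1 for a flat spectrum, 0 when
    all power sits in one bin. Invariant to scaling the spectrum by any
    positive constant; all-zero bins map to 0.
    """
    power = np.atleast_2d(spec.power)
    n_freq = power.shape[1]
    if n_freq < 2:
        raise ValueError("need at least 2 frequency bins for spectral entropy")
    totals = power.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    p = power / safe
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1) / np.log(n_freq)
    h[totals[:, 0] == 0] = 0.0
    return SpectralEntropyTrace(times=spec.times.copy(), values=h)
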