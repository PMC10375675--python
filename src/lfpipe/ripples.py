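"""Sharp-wave-ripple (SPW-R) detection and summarization.

The detection rule: the raw CA1 trace is band-pass filtered to the ripple
band (120–250 Hz, zero phase); the Hilbert envelope (absolute value of the
analytic signal) is thresholded at mean + 7 SD, with mean and SD taken over
the whole analyzed epoch. The trace is scanned in 300 ms windows advanced in
50 ms steps; a candidate crossing is accepted only if the envelope stays
above mean + 3 SD for at least 10 ms after the crossing (artifact rejection).
Event extent is the surrounding interval where the envelope exceeds the 3 SD
threshold; events separated by less than 30 ms are merged. Per event the
peak-to-peak amplitude is read from the ripple-band trace, and a recording is
summarized by the median amplitude and the event rate (events/min).

``detect_ripples_bruteforce`` implements the same rules sample-by-sample with
no windowing; the windowed scan is an implementation device and must yield
identical events — the equivalence is enforced by tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recio import BandDef

__all__ = [
    "DetectorSettings",
    "RippleEvent",
    "RippleSummary",
    "bandpass_ripple",
    "envelope",
    "detect_ripples",
    "detect_ripples_bruteforce",
    "summarize_ripples",
]

RIPPLE_BAND = (120.0, 250.0)


@dataclass(frozen=True)
class DetectorSettings:
    band: tuple[float, float] = RIPPLE_BAND
    detect_sd: float = 7.0       # detection threshold, SD above envelope mean
    sustain_sd: float = 3.0      # sustain threshold after the crossing
    sustain_ms: float = 10.0     # required time above sustain threshold
    merge_ms: float = 30.0       # events closer than this are one event
    scan_window_ms: float = 300.0
    scan_step_ms: float = 50.0
    edge_exclude_s: float = 0.5  # filter/Hilbert edge guard

    def __post_init__(self) -> None:
        if self.sustain_sd >= self.detect_sd:
            raise ValueError("sustain_sd must be below detect_sd")
        for name in ("sustain_ms", "merge_ms", "scan_window_ms", "scan_step_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class RippleEvent:
    t_start: float         # s
    t_end: float           # s
    peak_envelope: float   # envelope peak in SD units above mean
    peak_to_peak: float    # µV, measured on the ripple-band trace

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


@dataclass
class RippleSummary:
    n_events: int
    event_rate: float              # events/min
    median_amplitude: float | None  # µV; None when no events
    duration_s: float
    settings: DetectorSettings | None = None


def bandpass_ripple(signal: np.ndarray, fs: float,
                    band: tuple[float, float] | BandDef = RIPPLE_BAND) -> np.ndarray:
    """Zero-phase FIR band-pass to the ripple band."""
    if isinstance(band, BandDef):
        band = (band.f_lo, band.f_hi)
    f_lo, f_hi = band
    nyq = fs / 2.0
    if f_hi >= nyq:
        raise ValueError(f"band upper edge {f_hi} Hz >= Nyquist ({nyq} Hz)")
    width = min(30.0, f_lo / 2.0) / nyq
    numtaps, beta = sps.kaiserord(ripple=65.0, width=width)
    numtaps |= 1
    # cutoffs placed half a transition width outside the band so the passband
    # itself stays flat (firwin cutoffs are -6 dB points)
    half = width * nyq / 2.0
    taps = sps.firwin(numtaps, [(f_lo - half) / nyq, (f_hi + half) / nyq],
                      pass_zero=False, window=("kaiser", beta))
    x = np.asarray(signal, dtype=np.float64)
    padlen = min(3 * numtaps, x.size - 1)
    return sps.filtfilt(taps, 1.0, x, padtype="odd", padlen=padlen)


def envelope(filtered: np.ndarray, fs: float) -> tuple[np.ndarray, float, float]:
    """Hilbert envelope of a band-limited trace with its epoch mean and SD."""
    x = np.asarray(filtered, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty trace")
    env = np.abs(sps.hilbert(x))
    return env, float(env.mean()), float(env.std())


# ---------------------------------------------------------------------------
# event building shared by both detector implementations
# ---------------------------------------------------------------------------

def _events_from_crossings(env: np.ndarray, filtered: np.ndarray, fs: float,
                           accepted: list[int], lo: float, mu: float, sd: float,
                           merge_n: int) -> list[RippleEvent]:
    above_lo = env > lo
    n = env.size
    spans: list[tuple[int, int]] = []
    for c in accepted:
        s = c
        while s > 0 and above_lo[s - 1]:
            s -= 1
        e = c
        while e + 1 < n and above_lo[e + 1]:
            e += 1
        if not spans or s > spans[-1][1]:
            spans.append((s, e))
        # crossings inside an already-built span add nothing
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - (merged[-1][1] + 1) < merge_n:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        seg = filtered[s:e + 1]
        peak_sd = (env[s:e + 1].max() - mu) / sd
        events.append(RippleEvent(t_start=s / fs, t_end=(e + 1) / fs,
                                  peak_envelope=float(peak_sd),
                                  peak_to_peak=float(seg.max() - seg.min())))
    return events


def _sustained(env: np.ndarray, c: int, lo: float, n_sustain: int) -> bool:
    if c + n_sustain > env.size:
        return False
    return bool(np.all(env[c:c + n_sustain] > lo))


def detect_ripples(filtered: np.ndarray, fs: float,
                   settings: DetectorSettings = DetectorSettings(),
                   ) -> list[RippleEvent]:
    """Windowed-scan SPW-R detector on a ripple-band filtered trace."""
    x = np.asarray(filtered, dtype=np.float64)
    win = int(round(settings.scan_window_ms / 1000.0 * fs))
    step = int(round(settings.scan_step_ms / 1000.0 * fs))
    if x.size <= win:
        raise ValueError("trace shorter than the scan window")
    env, mu, sd = envelope(x, fs)
    if sd == 0:
        warnings.warn("constant trace: envelope SD is zero, no events detectable")
        return []
    hi = mu + settings.detect_sd * sd
    lo = mu + settings.sustain_sd * sd
    n = x.size
    edge = int(round(settings.edge_exclude_s * fs))
    n_sustain = int(round(settings.sustain_ms / 1000.0 * fs))
    merge_n = int(round(settings.merge_ms / 1000.0 * fs))

    # scan: mark every sample that exceeds the detection threshold in any window
    candidate = np.zeros(n, dtype=bool)
    starts = list(range(0, n - win + 1, step))
    if starts[-1] != n - win:
        starts.append(n - win)  # tail window so the scan tiles the whole trace
    over = env > hi
    for s in starts:
        candidate[s:s + win] |= over[s:s + win]
    candidate[:edge] = False
    candidate[n - edge:] = False

    # crossings: first sample of each contiguous candidate run
    idx = np.flatnonzero(candidate)
    if idx.size == 0:
        return []
    run_starts = idx[np.concatenate([[True], np.diff(idx) > 1])]
    accepted = [int(c) for c in run_starts if _sustained(env, int(c), lo, n_sustain)]
    return _events_from_crossings(env, x, fs, accepted, lo, mu, sd, merge_n)


def detect_ripples_bruteforce(filtered: np.ndarray, fs: float,
                              settings: DetectorSettings = DetectorSettings(),
                              ) -> list[RippleEvent]:
    """Sample-wise reference implementation of the same detection rules.

    Walks the envelope one sample at a time with no window scanning or
    vectorized run detection; kept deliberately naive as the verification
    oracle for :func:`detect_ripples`.
    """
    x = np.asarray(filtered, dtype=np.float64)
    win = int(round(settings.scan_window_ms / 1000.0 * fs))
    if x.size <= win:
        raise ValueError("trace shorter than the scan window")
    env, mu, sd = envelope(x, fs)
    if sd == 0:
        warnings.warn("constant trace: envelope SD is zero, no events detectable")
        return []
    hi = mu + settings.detect_sd * sd
    lo = mu + settings.sustain_sd * sd
    n = x.size
    edge = int(round(settings.edge_exclude_s * fs))
    n_sustain = int(round(settings.sustain_ms / 1000.0 * fs))
    merge_n = int(round(settings.merge_ms / 1000.0 * fs))

    accepted = []
    prev_over = False
    for i in range(edge, n - edge):
        over = env[i] > hi
        if over and not prev_over:
            ok = i + n_sustain <= n
            if ok:
                for j in range(i, i + n_sustain):
                    if env[j] <= lo:
                        ok = False
                        break
            if ok:
                accepted.append(i)
        prev_over = over
    return _events_from_crossings(env, x, fs, accepted, lo, mu, sd, merge_n)


def summarize_ripples(events: list[RippleEvent], duration_s: float,
                      settings: DetectorSettings | None = None) -> RippleSummary:
    """Median peak-to-peak amplitude and event rate over the sampling period."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = len(events)
    median = float(np.median([e.peak_to_peak for e in events])) if n else None
    return RippleSummary(n_events=n, event_rate=n / (duration_s / 60.0),
                         median_amplitude=median, duration_s=duration_s,
                         settings=settings)
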