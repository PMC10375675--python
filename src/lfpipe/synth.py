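"""Synthetic LFP/ECoG generator with ground truth.

Emulates the statistical structure the analysis pipeline assumes: multichannel
1/f background noise, four oscillatory cortical modes, scheduled mode
transitions, CA1 sharp-wave-ripple transients (120–250 Hz bursts riding on a
slow deflection), and matching locomotion trajectories with immobile epochs.

The four default modes are:

* mode I   — awake/mobile: theta (4–12 Hz) peak plus gamma, locomotion on;
* mode II  — slow-wave sleep: large slow oscillation with 0.5–1 Hz up–down
  amplitude alternation of the broadband component, immobile;
* mode III — REM-like: theta-dominant but immobile;
* mode IV  — inflammation-like: broadband attenuation relative to mode II with
  relative enhancement near 3 Hz (and a weaker ~6 Hz component), immobile.

Everything is deterministic given (config, seed): random streams are derived
from ``np.random.default_rng([seed, ...])`` keys, so regenerating any part of
a recording yields bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .recio import Channel, Recording

__all__ = [
    "ModeSpec",
    "RippleParams",
    "SimulationConfig",
    "GroundTruth",
    "MODE_PRESETS",
    "generate_mode_epoch",
    "inject_ripples",
    "generate_recording",
    "generate_trajectory",
]

MODE_LABELS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ModeSpec:
    """Spectral signature of one cortical mode.

    ``oscillators`` is a list of (center_hz, bandwidth_hz, relative_amplitude)
    narrowband components added on top of the 1/f background;
    ``broadband_gain`` multiplies the background amplitude; ``updown_hz``, if
    set, square-wave-modulates the background amplitude to mimic up–down state
    alternation (producing 1–4 Hz power).
    """

    label: str
    oscillators: tuple[tuple[float, float, float], ...] = ()
    broadband_gain: float = 1.0
    motion_active: bool = False
    updown_hz: float | None = None

    def __post_init__(self) -> None:
        if self.label not in MODE_LABELS:
            raise ValueError(f"invalid mode label {self.label!r}; expected one of {MODE_LABELS}")
        if self.broadband_gain <= 0:
            raise ValueError("broadband_gain must be > 0")
        for f0, bw, amp in self.oscillators:
            if f0 <= 0 or bw <= 0:
                raise ValueError("oscillator center frequency and bandwidth must be > 0")
            if amp < 0:
                raise ValueError("oscillator amplitude must be >= 0")


MODE_PRESETS: dict[str, ModeSpec] = {
    # relative amplitudes are in units of the background RMS (noise_scale)
    "I": ModeSpec("I", oscillators=((6.0, 2.0, 2.5), (60.0, 40.0, 0.8)),
                  broadband_gain=1.0, motion_active=True),
    "II": ModeSpec("II", oscillators=((1.5, 1.0, 3.5),),
                   broadband_gain=1.0, motion_active=False, updown_hz=0.75),
    "III": ModeSpec("III", oscillators=((6.5, 2.0, 2.5), (80.0, 40.0, 0.4)),
                    broadband_gain=1.0, motion_active=False),
    "IV": ModeSpec("IV", oscillators=((3.0, 1.0, 1.2), (6.0, 1.5, 0.5)),
                   broadband_gain=0.45, motion_active=False),
}


@dataclass(frozen=True)
class RippleParams:
    """Generative parameters for sharp-wave-ripple transients on CA1 channels."""

    rate: float = 10.0               # events/min
    center_freq: float = 160.0       # Hz, within the 120–250 Hz ripple band
    duration_mean: float = 50.0      # ms (full-width, ±3 sigma of the burst window)
    amplitude_snr: float = 10.0      # envelope peak, multiples of background envelope SD
    mode_rate_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("ripple rate must be >= 0")
        if not (120.0 <= self.center_freq <= 250.0):
            raise ValueError("center_freq must lie in the 120–250 Hz ripple band")
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be > 0")


@dataclass
class SimulationConfig:
    """Full generative specification; doubles as the ground-truth record."""

    fs: float = 1000.0
    channels: tuple[tuple[str, str], ...] = (("ca1", "CA1"), ("ncx", "NCX"))
    schedule: tuple[tuple[ModeSpec, float], ...] = ()
    noise_exponent: float = 1.5      # background power ~ 1/f^alpha
    noise_scale: float = 50.0        # µV RMS of the unit-gain background
    ripple_params: RippleParams | None = None
    injection_time: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 500:
            raise ValueError("fs must exceed 500 Hz")
        if self.total_duration() <= 0:
            raise ValueError("schedule must have positive total duration")
        for mode, dur in self.schedule:
            if dur <= 0:
                raise ValueError(f"zero/negative duration for mode {mode.label}")
            for f0, _, _ in mode.oscillators:
                if f0 >= self.fs / 2:
                    raise ValueError(f"oscillator at {f0} Hz >= Nyquist ({self.fs/2} Hz)")

    def total_duration(self) -> float:
        return float(sum(d for _, d in self.schedule))

    # -- structured-text round trip ------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "fs": self.fs,
            "channels": [list(c) for c in self.channels],
            "schedule": [{"mode": asdict(m), "duration_s": dur}
                         for m, dur in self.schedule],
            "noise_exponent": self.noise_exponent,
            "noise_scale": self.noise_scale,
            "injection_time": self.injection_time,
            "seed": self.seed,
        }
        if self.ripple_params is not None:
            d["ripple_params"] = asdict(self.ripple_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        sched = []
        for entry in d.get("schedule", []):
            m = dict(entry["mode"])
            m["oscillators"] = tuple(tuple(o) for o in m.get("oscillators", ()))
            sched.append((ModeSpec(**m), float(entry["duration_s"])))
        rp = d.get("ripple_params")
        return cls(
            fs=float(d.get("fs", 1000.0)),
            channels=tuple((c[0], c[1]) for c in d.get("channels", [["ca1", "CA1"]])),
            schedule=tuple(sched),
            noise_exponent=float(d.get("noise_exponent", 1.5)),
            noise_scale=float(d.get("noise_scale", 50.0)),
            ripple_params=RippleParams(**rp) if rp else None,
            injection_time=float(d.get("injection_time", 0.0)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """What the generator actually produced, for detector/classifier scoring."""

    mode_intervals: list[tuple[str, float, float]]          # (label, t0, t1)
    ripple_intervals: dict[str, list[tuple[float, float]]]  # channel -> [(t0, t1)]
    switch_time: float | None                               # first transition into mode IV
    immobile_epochs: list[tuple[float, float]]

    def labels_at(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, "unknown", dtype=object)
        for label, t0, t1 in self.mode_intervals:
            out[(times >= t0) & (times < t1)] = label
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mode_intervals": self.mode_intervals,
            "ripple_intervals": self.ripple_intervals,
            "switch_time": self.switch_time,
            "immobile_epochs": self.immobile_epochs,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            mode_intervals=[tuple(x) for x in d["mode_intervals"]],
            ripple_intervals={k: [tuple(i) for i in v]
                              for k, v in d["ripple_intervals"].items()},
            switch_time=d["switch_time"],
            immobile_epochs=[tuple(x) for x in d["immobile_epochs"]],
        )


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _shaped_noise(n: int, fs: float, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^alpha, unit RMS."""
    white = rng.standard_normal(n)
    if alpha == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _narrowband(n: int, fs: float, f0: float, bw: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrowband Gaussian noise: Gaussian spectral profile at f0."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    sigma = bw / 2.0
    profile = np.exp(-0.5 * ((f - f0) / sigma) ** 2)
    x = np.fft.irfft(spec * profile, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def generate_mode_epoch(mode: ModeSpec, duration: float, fs: float,
                        rng: np.random.Generator, *,
                        noise_exponent: float = 1.5,
                        noise_scale: float = 50.0) -> np.ndarray:
    """One voltage epoch (µV) with the mode's spectral signature."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    for f0, _, _ in mode.oscillators:
        if f0 >= fs / 2:
            raise ValueError(f"oscillator at {f0} Hz >= Nyquist ({fs/2} Hz)")
    n = int(round(duration * fs))
    bg = _shaped_noise(n, fs, noise_exponent, rng) * noise_scale * mode.broadband_gain
    if mode.updown_hz is not None:
        t = np.arange(n) / fs
        square = np.sign(np.sin(2 * np.pi * mode.updown_hz * t))
        bg *= 0.625 + 0.375 * square  # alternate between 1.0 (up) and 0.25 (down)
    trace = bg
    for f0, bw, amp in mode.oscillators:
        if amp > 0:
            trace = trace + _narrowband(n, fs, f0, bw, rng) * amp * noise_scale
    return trace


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for t0, t1 in intervals[1:]:
        if t0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t1)
        else:
            merged.append([t0, t1])
    return [tuple(iv) for iv in merged]


def inject_ripples(trace: np.ndarray, fs: float, params: RippleParams,
                   rng: np.random.Generator,
                   ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Superpose Gaussian-windowed ripple-band bursts on ``trace``.

    Each event is a ``center_freq`` sinusoid under a Gaussian window, riding
    on a slow negative deflection that mimics the sharp wave. The shared
    burst amplitude is calibrated by fixed-point iteration so that event
    envelope peaks land ``amplitude_snr`` standard deviations above the mean
    of the *injected* trace's ripple-band envelope — the same "+N SD above
    mean" statistics a threshold detector computes over the analyzed epoch
    (which necessarily include the events themselves). Returns the augmented
    trace and the merged ground-truth event intervals in seconds.
    """
    if fs <= 2 * params.center_freq:
        raise ValueError("fs must exceed twice the ripple center frequency")
    duration = len(trace) / fs
    n_events = rng.poisson(params.rate * duration / 60.0)
    if n_events == 0:
        return trace, []

    from .ripples import bandpass_ripple, envelope

    trace = np.asarray(trace, dtype=np.float64)
    t = np.arange(len(trace)) / fs
    margin = 0.3
    intervals = []
    centers = np.sort(rng.uniform(margin, max(duration - margin, margin), n_events))
    burst = np.zeros_like(trace)       # unit-amplitude ripple bursts
    deflection = np.zeros_like(trace)  # unit-amplitude slow sharp waves
    for t0 in centers:
        dur_s = params.duration_mean / 1000.0 * rng.uniform(0.8, 1.2)
        sigma = dur_s / 6.0
        phase = rng.uniform(0, 2 * np.pi)
        window = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        burst += window * np.cos(2 * np.pi * params.center_freq * (t - t0) + phase)
        deflection -= 1.5 * np.exp(-0.5 * ((t - t0) / (3 * sigma)) ** 2)
        intervals.append((max(t0 - 3 * sigma, 0.0), min(t0 + 3 * sigma, duration)))

    _, mu, sd = envelope(bandpass_ripple(trace, fs, (120.0, 250.0)), fs)
    if sd == 0:
        mu, sd = 0.0, 1.0
    amp = mu + params.amplitude_snr * sd
    for _ in range(2):  # converges fast: event duty cycle is small
        out = trace + amp * (burst + deflection)
        _, mu, sd = envelope(bandpass_ripple(out, fs, (120.0, 250.0)), fs)
        amp = mu + params.amplitude_snr * sd
    out = trace + amp * (burst + deflection)
    return out, _merge_intervals(intervals)


def generate_recording(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Synthesize a multichannel recording plus its ground truth."""
    fs = config.fs
    total = config.total_duration()
    n_total = int(round(fs * total))

    # sample-aligned epoch boundaries
    edges_s = np.concatenate([[0.0], np.cumsum([d for _, d in config.schedule])])
    edges = np.round(edges_s * fs).astype(int)
    edges[-1] = n_total

    mode_intervals = [(m.label, float(edges[j] / fs), float(edges[j + 1] / fs))
                      for j, (m, _) in enumerate(config.schedule)]
    switch_time = None
    for j, (m, _) in enumerate(config.schedule):
        if m.label == "IV" and (j == 0 or config.schedule[j - 1][0].label != "IV"):
            switch_time = float(edges[j] / fs)
            break
    immobile = _merge_intervals([(t0, t1) for (m, _), (lab, t0, t1)
                                 in zip(config.schedule, mode_intervals)
                                 if not m.motion_active])

    data = np.empty((len(config.channels), n_total))
    ripple_truth: dict[str, list[tuple[float, float]]] = {}
    for i, (label, region) in enumerate(config.channels):
        pieces = []
        events: list[tuple[float, float]] = []
        for j, (mode, _) in enumerate(config.schedule):
            n_epoch = edges[j + 1] - edges[j]
            rng = np.random.default_rng([config.seed, i, j])
            epoch = generate_mode_epoch(mode, n_epoch / fs, fs, rng,
                                        noise_exponent=config.noise_exponent,
                                        noise_scale=config.noise_scale)
            if (region == "CA1" and config.ripple_params is not None
                    and config.ripple_params.rate > 0):
                rp = config.ripple_params
                scale = rp.mode_rate_scale.get(mode.label, 1.0)
                if scale > 0:
                    scaled = RippleParams(rate=rp.rate * scale,
                                          center_freq=rp.center_freq,
                                          duration_mean=rp.duration_mean,
                                          amplitude_snr=rp.amplitude_snr)
                    rng_r = np.random.default_rng([config.seed, i, j, 7])
                    epoch, ivs = inject_ripples(epoch, fs, scaled, rng_r)
                    offset = edges[j] / fs
                    events.extend((t0 + offset, t1 + offset) for t0, t1 in ivs)
            pieces.append(epoch)
        data[i] = np.concatenate(pieces)
        if region == "CA1" and config.ripple_params is not None:
            ripple_truth[label] = _merge_intervals(events)

    channels = [Channel(label, region) for label, region in config.channels]
    rec = Recording(data, fs, channels,
                    markers={"injection": config.injection_time},
                    notes={"generator": "lfpipe.synth", "seed": config.seed})
    truth = GroundTruth(mode_intervals, ripple_truth, switch_time, immobile)
    return rec, truth


# ---------------------------------------------------------------------------
# locomotion trajectories
# ---------------------------------------------------------------------------

def generate_trajectory(schedule, frame_rate: float, arena_px: float,
                        rng: np.random.Generator, *,
                        mobile_step_px: float = 3.0,
                        immobile_step_px: float = 0.0005,
                        bodypart: str = "back"):
    """Random-walk pose trajectory matching a mode schedule.

    During ``motion_active`` modes the tracked point performs a reflected
    Gaussian random walk (``mobile_step_px`` per frame and axis); otherwise it
    jitters in place. Likelihood emulates a well-trained pose estimator:
    near 1 with rare dips.
    """
    from .motion import Trajectory

    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    schedule = list(schedule)
    if not schedule:
        return Trajectory(times=np.empty(0), x=np.empty(0), y=np.empty(0),
                          likelihood=np.empty(0), bodypart=bodypart,
                          frame_rate=frame_rate)
    total = sum(d for _, d in schedule)
    n_frames = int(round(total * frame_rate))
    mobile = np.zeros(n_frames, dtype=bool)
    edges = np.round(np.concatenate([[0.0], np.cumsum([d for _, d in schedule])])
                     * frame_rate).astype(int)
    edges[-1] = n_frames
    for j, (mode, _) in enumerate(schedule):
        mobile[edges[j]:edges[j + 1]] = mode.motion_active

    steps = np.where(mobile[:, None], mobile_step_px, immobile_step_px) \
        * rng.standard_normal((n_frames, 2))
    pos = np.empty((n_frames, 2))
    pos[0] = arena_px / 2.0
    for k in range(1, n_frames):
        pos[k] = pos[k - 1] + steps[k]
    # reflect into the arena
    pos = np.abs(pos)
    pos = arena_px - np.abs(arena_px - pos % (2 * arena_px))
    likelihood = np.clip(1.0 - rng.exponential(0.003, n_frames), 0.0, 1.0)
    return Trajectory(times=np.arange(n_frames) / frame_rate,
                      x=pos[:, 0], y=pos[:, 1], likelihood=likelihood,
                      bodypart=bodypart, frame_rate=frame_rate)
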