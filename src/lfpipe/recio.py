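"""Recording containers, native-container / EDF input, and anti-aliased downsampling.

The native container is deliberately plain: one little-endian float32 matrix
(channels x samples) on disk next to a JSON sidecar holding sampling rate,
channel labels/regions, event markers and free-form provenance notes. This
keeps recordings self-describing and greppable without a proprietary reader.
Voltages are treated as microvolts (µV) throughout the package; EDF physical
dimensions are honored on import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDef",
    "Channel",
    "Recording",
    "read_recording",
    "write_recording",
    "read_edf",
    "downsample",
]

REGIONS = ("CA1", "NCX", "DG")


@dataclass(frozen=True)
class BandDef:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"band {self.name}: need 0 < f_lo < f_hi, got "
                             f"[{self.f_lo}, {self.f_hi}]")


# Canonical bands used in the analyses (hippocampal CA1 vs neocortical ECoG
# gamma differ because the epidural screw electrode does not resolve >60 Hz).
BANDS = {
    "theta": BandDef("theta", 4.0, 12.0),
    "theta_central": BandDef("theta_central", 5.0, 8.0),
    "delta": BandDef("delta", 1.0, 4.0),
    "slow_delta": BandDef("slow_delta", 1.0, 2.0),
    "supratheta": BandDef("supratheta", 10.0, 20.0),
    "gamma_ca1": BandDef("gamma_ca1", 30.0, 140.0),
    "gamma_ncx": BandDef("gamma_ncx", 30.0, 60.0),
    "low_ncx": BandDef("low_ncx", 2.0, 8.0),
    "ripple": BandDef("ripple", 120.0, 250.0),
    "broadband": BandDef("broadband", 1.0, 140.0),
    "full": BandDef("full", 1.0, 200.0),
}


@dataclass(frozen=True)
class Channel:
    label: str
    region: str = "CA1"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")


@dataclass
class Recording:
    """Multichannel voltage time-series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in µV.
    fs : float
        Sampling rate in Hz.
    channels : list of Channel
        One entry per row of ``data``.
    markers : dict
        Named event times in seconds (e.g. ``{"injection": 0.0}``).
    notes : dict
        Free-form provenance metadata.
    """

    data: np.ndarray
    fs: float
    channels: list[Channel]
    markers: dict[str, float] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel descriptors for {self.data.shape[0]} data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = self.duration
        for name, t in self.markers.items():
            if not (0 <= t <= dur):
                raise ValueError(f"marker {name!r} at {t} s outside [0, {dur}] s")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.label == label:
                return i
        raise KeyError(f"no channel labeled {label!r}")

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def channels_in_region(self, region: str) -> list[str]:
        return [ch.label for ch in self.channels if ch.region == region]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as float32 matrix + JSON sidecar; returns the data path."""
    path = Path(path)
    if path.suffix == ".json":
        raise ValueError("pass the data path, not the sidecar path")
    path.parent.mkdir(parents=True, exist_ok=True)
    rec.data.astype("<f4").tofile(path)
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "units": "uV",
        "channels": [{"label": c.label, "region": c.region} for c in rec.channels],
        "markers": rec.markers,
        "notes": rec.notes,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_native(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "n_channels", "n_samples", "channels"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing field {key!r}")
    raw = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
    expect = meta["n_channels"] * meta["n_samples"]
    if raw.size != expect:
        raise ValueError(
            f"{path}: file holds {raw.size} values, sidecar field 'n_samples' implies {expect}")
    data = raw.reshape(meta["n_channels"], meta["n_samples"]).astype(np.float64)
    chans = [Channel(c["label"], c.get("region", "CA1")) for c in meta["channels"]]
    return Recording(data, float(meta["fs"]), chans,
                     markers=dict(meta.get("markers", {})),
                     notes=dict(meta.get("notes", {})))


def read_edf(path: str | Path, region_map: dict[str, str] | None = None) -> Recording:
    """Import an EDF/EDF+ file. Voltages converted to µV; equal rates required."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns SI volts
    region_map = region_map or {}
    chans = [Channel(name, region_map.get(name, "CA1")) for name in raw.ch_names]
    return Recording(data, float(raw.info["sfreq"]), chans,
                     notes={"source": str(path), "format": "EDF"})


def read_recording(path: str | Path, format: str = "native",
                   **kwargs) -> Recording:
    """Read a recording; ``format`` is ``"native"`` or ``"edf"``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native":
        return _read_native(path)
    if format == "edf":
        return read_edf(path, **kwargs)
    raise ValueError(f"unknown format {format!r}")


def _design_antialias(fs: float, target_fs: float) -> np.ndarray:
    # Zero-phase application via filtfilt doubles the stopband attenuation,
    # so a 60 dB one-pass design comfortably exceeds the 40 dB contract.
    nyq = fs / 2.0
    cutoff = 0.45 * target_fs
    width = 0.1 * target_fs / nyq
    numtaps, beta = sps.kaiserord(ripple=65.0, width=width)
    numtaps |= 1  # odd length keeps the filter type-I (symmetric)
    return sps.firwin(numtaps, cutoff / nyq, window=("kaiser", beta))


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased downsampling to ``target_fs`` (zero-phase low-pass, then decimate).

    Integer decimation factors are handled by direct sample picking after the
    zero-phase low-pass; rational ratios fall back to polyphase resampling of
    the pre-filtered signal.
    """
    if target_fs >= rec.fs:
        raise ValueError(f"target_fs {target_fs} must be below fs {rec.fs}")
    taps = _design_antialias(rec.fs, target_fs)
    filtered = sps.filtfilt(taps, 1.0, rec.data, axis=1, padtype="odd",
                            padlen=min(3 * len(taps), rec.n_samples - 1))
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        out = filtered[:, :: int(round(ratio))]
    else:
        from fractions import Fraction

        frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
        out = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    new = Recording(out, target_fs, list(rec.channels),
                    markers=dict(rec.markers), notes=dict(rec.notes))
    new.notes["downsampled_from_hz"] = rec.fs
    return new
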