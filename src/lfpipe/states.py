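"""Cortical-mode segmentation (modes I–IV), prevalence, and switch detection.

Segmentation is rule-based on per-bin spectral features plus motion:

* theta dominance: central-theta (5–8 Hz) power / delta (1–4 Hz) power > 1.5;
* mode I  = mobile and theta-dominant;
* mode III = immobile and theta-dominant (REM-like);
* mode IV = immobile, not theta-dominant, with broadband (1–140 Hz) power
  below 0.6 × the slow-wave (mode II) reference median — the inflammation-like
  state is defined *relative* to slow-wave sleep;
* mode II = everything else immobile.

Labels are smoothed with a 5-bin majority filter to suppress single-bin
flicker. If the reference median is not supplied it is self-calibrated from a
provisional pass (median broadband power over immobile, non-theta bins).
Classification uses only power ratios and relative powers, so rescaling the
whole recording leaves labels unchanged once the reference is recomputed.

The post-injection switch is detected on a baseline-normalized band-power
series (typically gamma) as the earliest bin where power stays below
(1 − drop_frac) of baseline for a sustained run of bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .spectral import BandPowerSeries, Spectrogram, band_power, normalize_power
from .recio import BANDS

__all__ = [
    "ModeFeatures",
    "ModeSegmentation",
    "SwitchResult",
    "compute_mode_features",
    "classify_modes",
    "mode_prevalence",
    "detect_switch",
    "group_switch_trace",
    "rem_present",
]

MODE_LABELS = ("I", "II", "III", "IV")


@dataclass
class ModeFeatures:
    """Per-bin features feeding the mode classifier."""

    times: np.ndarray
    theta: np.ndarray        # 5–8 Hz band power, µV²
    delta: np.ndarray        # 1–4 Hz
    low3: np.ndarray         # 3–4 Hz (relative-enhancement readout for mode IV)
    broadband: np.ndarray    # 1–140 Hz (clipped to the spectrogram's range)
    speed: np.ndarray | None = None   # px/s (or cm/s), aligned to bins


@dataclass
class ModeSegmentation:
    times: np.ndarray
    labels: np.ndarray       # object array over {"I","II","III","IV","unknown"}
    features: ModeFeatures
    settings: dict = field(default_factory=dict)

    def intervals(self) -> list[tuple[float, float, str]]:
        """Contiguous same-label runs as (t_start, t_end, label), BED-style."""
        out = []
        if self.times.size == 0:
            return out
        step = float(np.median(np.diff(self.times))) if self.times.size > 1 else 1.0
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                out.append((float(self.times[start] - step / 2),
                            float(self.times[i - 1] + step / 2),
                            str(self.labels[start])))
                start = i
        return out


@dataclass
class SwitchResult:
    switch_time: float | None
    rule: str
    times: np.ndarray
    normalized: np.ndarray   # baseline-normalized band power per bin
    below: np.ndarray        # boolean per-bin drop indicator


def compute_mode_features(spec: Spectrogram,
                          speed: np.ndarray | None = None) -> ModeFeatures:
    """Band powers (and optional motion speed) per spectrogram bin."""
    f_hi = float(spec.freqs[-1])
    bb_hi = min(140.0, f_hi)
    from .recio import BandDef

    def bp(lo, hi, name):
        return band_power(spec, BandDef(name, lo, hi)).values

    if speed is not None and len(speed) != len(spec.times):
        raise ValueError("speed must be aligned to spectrogram bins")
    return ModeFeatures(
        times=spec.times.copy(),
        theta=bp(BANDS["theta_central"].f_lo, BANDS["theta_central"].f_hi, "theta"),
        delta=bp(BANDS["delta"].f_lo, BANDS["delta"].f_hi, "delta"),
        low3=bp(3.0, 4.0, "low3"),
        broadband=bp(1.0, bb_hi, "broadband"),
        speed=None if speed is None else np.asarray(speed, dtype=float),
    )


def _majority_filter(labels: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or labels.size == 0:
        return labels
    half = k // 2
    out = labels.copy()
    for i in range(labels.size):
        lo, hi = max(0, i - half), min(labels.size, i + half + 1)
        window = labels[lo:hi]
        vals, counts = np.unique(window, return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        if labels[i] not in winners:  # ties keep the original label
            out[i] = winners[0]
    return out


def classify_modes(features: ModeFeatures, *,
                   reference_broadband: float | None = None,
                   theta_ratio_min: float = 1.5,
                   mobility_speed_min: float = 25.0,
                   mode_iv_power_frac: float = 0.6,
                   smooth_bins: int = 5) -> ModeSegmentation:
    """Label each bin with a cortical mode.

    ``mobility_speed_min`` is in the speed series' own units (px/s by default;
    25 px/s ≈ 1 px per frame at 25 fps). When no speed series is available the
    I/III distinction is impossible and theta-dominant bins are labeled
    ``"theta-state"``.
    """
    n = features.times.size
    labels = np.full(n, "unknown", dtype=object)
    total = features.broadband
    valid = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_ratio = np.where(features.delta > 0,
                               features.theta / features.delta, np.inf)
    theta_dom = valid & (theta_ratio > theta_ratio_min)

    if reference_broadband is None:
        # self-calibration: slow-wave bins are immobile and delta-dominant
        if features.speed is not None:
            immobile = features.speed <= mobility_speed_min
        else:
            immobile = np.ones(n, dtype=bool)
        sws_like = valid & immobile & ~theta_dom
        if not sws_like.any():
            raise ValueError("cannot self-calibrate mode II reference: "
                             "no immobile non-theta bins")
        reference_broadband = float(np.median(total[sws_like]))

    attenuated = valid & (total < mode_iv_power_frac * reference_broadband)
    if features.speed is not None:
        mobile = features.speed > mobility_speed_min
        labels[theta_dom & mobile] = "I"
        labels[theta_dom & ~mobile] = "III"
    else:
        labels[theta_dom] = "theta-state"
    labels[valid & ~theta_dom & attenuated] = "IV"
    labels[valid & ~theta_dom & ~attenuated] = "II"

    labels = _majority_filter(labels, smooth_bins)
    return ModeSegmentation(times=features.times.copy(), labels=labels,
                            features=features,
                            settings={"reference_broadband": reference_broadband,
                                      "theta_ratio_min": theta_ratio_min,
                                      "mobility_speed_min": mobility_speed_min,
                                      "mode_iv_power_frac": mode_iv_power_frac,
                                      "smooth_bins": smooth_bins})


def mode_prevalence(seg: ModeSegmentation,
                    window: tuple[float, float] | None = None) -> dict[str, float]:
    """Fraction of labeled bins per mode within ``window`` (sums to 1)."""
    mask = np.ones(seg.times.size, dtype=bool)
    if window is not None:
        t0, t1 = window
        mask = (seg.times >= t0) & (seg.times <= t1)
    if not mask.any():
        raise ValueError("window does not overlap the segmentation")
    labels = seg.labels[mask]
    labeled = labels[labels != "unknown"]
    if labeled.size == 0:
        return {}
    vals, counts = np.unique(labeled, return_counts=True)
    return {str(v): float(c) / labeled.size for v, c in zip(vals, counts)}


def detect_switch(series: BandPowerSeries, baseline: tuple[float, float], *,
                  drop_frac: float = 0.3, sustain_bins: int = 10) -> SwitchResult:
    """Earliest sustained band-power drop below (1 − drop_frac) × baseline."""
    t0, t1 = baseline
    norm = normalize_power(series, baseline)
    below = norm.values < (1.0 - drop_frac)
    # search only after the baseline window
    below[norm.times <= t1] = False
    switch = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= sustain_bins:
            switch = float(norm.times[i - sustain_bins + 1])
            break
    return SwitchResult(switch_time=switch,
                        rule=f"drop>{drop_frac:.0%} sustained {sustain_bins} bins",
                        times=norm.times, normalized=norm.values, below=below)


def group_switch_trace(group_a: list[BandPowerSeries],
                       group_b: list[BandPowerSeries], *,
                       equal_var: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise two-sided unpaired t-test between two groups of band-power
    series (one per animal), bin by bin.

    Returns (times, t statistics, p values). No multiplicity correction is
    applied — the trace mirrors a per-bin significance readout and should be
    interpreted as such.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 series")
    times = group_a[0].times
    for s in group_a + group_b:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ValueError("all series must share bin times")
    a = np.vstack([s.values for s in group_a])
    b = np.vstack([s.values for s in group_b])
    t, p = spstats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    return times.copy(), np.asarray(t), np.asarray(p)


def rem_present(seg: ModeSegmentation, min_bout_bins: int = 3) -> bool:
    """True iff the segmentation contains a mode III bout of at least
    ``min_bout_bins`` consecutive bins."""
    run = 0
    for lab in seg.labels:
        run = run + 1 if lab == "III" else 0
        if run >= min_bout_bins:
            return True
    return False
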