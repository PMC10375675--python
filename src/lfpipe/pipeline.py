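"""End-to-end orchestration: simulate (or load) → preprocess → spectral →
ripples → states → motion → stats → report bundle.

Every stage writes plain files (native signal container, CSV/JSON tables)
into the output directory and registers them in a manifest with content
hashes, so any stage can be re-run or audited in isolation. Given the same
config and seed the bundle is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import recio, spectral, ripples, states, motion, stats
from .recio import BANDS, BandDef, Recording
from .synth import (GroundTruth, MODE_PRESETS, RippleParams, SimulationConfig,
                    generate_recording, generate_trajectory)

__all__ = ["RunConfig", "make_demo", "run_pipeline"]

log = logging.getLogger("lfpipe")


@dataclass
class RunConfig:
    outdir: Path
    simulation: SimulationConfig | None = None
    recording_path: Path | None = None
    pose_path: Path | None = None
    target_fs: float = 1000.0
    window_s: float = 30.0
    step_s: float = 3.0
    detector: ripples.DetectorSettings = field(default_factory=ripples.DetectorSettings)
    baseline_s: float = 300.0          # first 5 min after injection
    switch_drop_frac: float = 0.3
    switch_sustain_bins: int = 10
    frame_rate: float = 25.0
    arena_px: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.simulation is None) == (self.recording_path is None):
            raise ValueError("exactly one input source: simulation or recording_path")


def make_demo(*, switch_time: float = 600.0, total_duration: float = 1800.0,
              fs: float = 1000.0, ripple_rate: float = 10.0,
              ripple_suppression: float = 0.1, seed: int = 0,
              outdir: str | Path = "demo_out") -> RunConfig:
    """Packaged inflammation-like demo: a mobile theta/gamma baseline epoch
    that switches to the broadband-attenuated mode IV at ``switch_time``, with
    CA1 ripples present before the switch and suppressed after it."""
    if not (0 < switch_time < total_duration):
        raise ValueError("switch_time must fall inside the recording")
    sim = SimulationConfig(
        fs=fs,
        channels=(("ca1", "CA1"), ("ncx", "NCX")),
        schedule=((MODE_PRESETS["I"], switch_time),
                  (MODE_PRESETS["IV"], total_duration - switch_time)),
        ripple_params=RippleParams(rate=ripple_rate,
                                   mode_rate_scale={"IV": ripple_suppression}),
        injection_time=0.0,
        seed=seed,
    )
    return RunConfig(outdir=Path(outdir), simulation=sim, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json)."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "params": {
        "target_fs": config.target_fs, "window_s": config.window_s,
        "step_s": config.step_s, "baseline_s": config.baseline_s,
        "switch_drop_frac": config.switch_drop_frac,
        "switch_sustain_bins": config.switch_sustain_bins,
        "detector": vars(config.detector).copy() if hasattr(config.detector, "__dict__")
                    else {k: getattr(config.detector, k) for k in
                          ("band", "detect_sd", "sustain_sd", "sustain_ms",
                           "merge_ms", "scan_window_ms", "scan_step_ms",
                           "edge_exclude_s")},
        "seed": config.seed,
    }}

    def stage(name):
        t0 = time.perf_counter()
        manifest["stages"][name] = {"outputs": [], "seconds": None}

        def register(*paths):
            for p in paths:
                manifest["stages"][name]["outputs"].append(
                    {"path": p.name, "sha256": _sha256(p)})
            manifest["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name,
                     manifest["stages"][name]["seconds"])
        return register

    # -- 1. acquire ----------------------------------------------------------
    reg = stage("acquire")
    truth: GroundTruth | None = None
    traj = None
    if config.simulation is not None:
        rec, truth = generate_recording(config.simulation)
        rng_traj = np.random.default_rng([config.seed, 555])
        traj = generate_trajectory([(m, d) for m, d in config.simulation.schedule],
                                   config.frame_rate, config.arena_px, rng_traj)
        rec_path = recio.write_recording(rec, out / "recording.dat")
        truth.to_json(out / "ground_truth.json")
        pose_path = motion.write_dlc_csv(traj, out / "pose.csv")
        reg(rec_path, rec_path.with_suffix(".json"),
            out / "ground_truth.json", pose_path)
    else:
        rec = recio.read_recording(config.recording_path)
        if config.pose_path is not None:
            traj = motion.load_pose(config.pose_path, "back", config.frame_rate)
        reg()

    # -- 2. preprocess -------------------------------------------------------
    reg = stage("preprocess")
    if rec.fs > config.target_fs:
        rec = recio.downsample(rec, config.target_fs)
    ds_path = recio.write_recording(rec, out / "recording_ds.dat")
    reg(ds_path, ds_path.with_suffix(".json"))

    # -- 3. spectral ---------------------------------------------------------
    reg = stage("spectral")
    injection = rec.markers.get("injection", 0.0)
    baseline = (injection, injection + config.baseline_s)
    specs: dict[str, spectral.Spectrogram] = {}
    spectral_files = []
    for ch in rec.channels:
        f_hi = 140.0 if ch.region != "NCX" else 60.0
        spec = spectral.multitaper_spectrogram(
            rec.get(ch.label), rec.fs, window_s=config.window_s,
            step_s=config.step_s, band=(1.0, min(f_hi, rec.fs / 2 * 0.9)))
        specs[ch.label] = spec
        gamma = BANDS["gamma_ca1"] if ch.region != "NCX" else BANDS["gamma_ncx"]
        broadband = BandDef("broadband", 1.0, float(spec.freqs[-1]))
        rows = {"time_s": spec.times}
        for band in (gamma, BANDS["theta_central"], BANDS["delta"], broadband):
            bp = spectral.band_power(spec, band)
            rows[f"{band.name}_uv2"] = bp.values
            rows[f"{band.name}_norm"] = spectral.normalize_power(bp, baseline).values
        rows["spectral_entropy"] = spectral.spectral_entropy(spec).values
        p = out / f"spectral_{ch.label}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        spectral_files.append(p)
    reg(*spectral_files)

    # -- 4. ripples ----------------------------------------------------------
    reg = stage("ripples")
    ca1 = rec.channels_in_region("CA1")
    if ca1:
        trace = rec.get(ca1[0])
        filt = ripples.bandpass_ripple(trace, rec.fs, config.detector.band)
        events = ripples.detect_ripples(filt, rec.fs, config.detector)
        summary = ripples.summarize_ripples(events, rec.duration, config.detector)
        ev_path = out / "ripple_events.csv"
        pd.DataFrame([{"t_start_s": e.t_start, "t_end_s": e.t_end,
                       "peak_envelope_sd": e.peak_envelope,
                       "p2p_uv": e.peak_to_peak} for e in events]).to_csv(
            ev_path, index=False)
        sm_path = out / "ripple_summary.json"
        sm_path.write_text(json.dumps({
            "channel": ca1[0], "n_events": summary.n_events,
            "event_rate_per_min": summary.event_rate,
            "median_amplitude_uv": summary.median_amplitude,
            "duration_s": summary.duration_s}, indent=1))
        reg(ev_path, sm_path)
        manifest["stages"]["ripples"]["channel"] = ca1[0]
    else:
        manifest["stages"]["ripples"]["skipped"] = "no CA1 channel"
        reg()

    # -- 5. states -----------------------------------------------------------
    reg = stage("states")
    state_ch = ca1[0] if ca1 else rec.channels[0].label
    spec = specs[state_ch]
    speed_series = (motion.speed_at(traj, spec.times, config.window_s)
                    if traj is not None and traj.n_frames else None)
    feats = states.compute_mode_features(spec, speed_series)
    # mode IV is defined by attenuation relative to a pre-switch reference;
    # anchor it on the baseline window's median broadband power
    base_mask = (spec.times >= baseline[0]) & (spec.times <= baseline[1])
    ref = float(np.median(feats.broadband[base_mask])) if base_mask.any() else None
    seg = states.classify_modes(feats, reference_broadband=ref)
    seg_path = out / "mode_segments.csv"
    pd.DataFrame(seg.intervals(),
                 columns=["t_start_s", "t_end_s", "label"]).to_csv(
        seg_path, index=False)
    gamma_bp = spectral.band_power(spec, BandDef("gamma", 30.0,
                                                 min(140.0, spec.freqs[-1])))
    sw = states.detect_switch(gamma_bp, baseline,
                              drop_frac=config.switch_drop_frac,
                              sustain_bins=config.switch_sustain_bins)
    sw_path = out / "switch.json"
    sw_path.write_text(json.dumps({
        "channel": state_ch, "switch_time_s": sw.switch_time, "rule": sw.rule,
        "rem_present": states.rem_present(seg),
        "prevalence": states.mode_prevalence(seg)}, indent=1))
    reg(seg_path, sw_path)

    # -- 6. motion -----------------------------------------------------------
    reg = stage("motion")
    if traj is not None and traj.n_frames >= 2:
        dist = motion.cumulative_distance(traj)
        m_path = out / "cumulative_distance.csv"
        pd.DataFrame({"time_s": traj.times, "cumulative_px": dist}).to_csv(
            m_path, index=False)
        reg(m_path)
    else:
        manifest["stages"]["motion"]["skipped"] = "no trajectory"
        reg()

    # -- 7. stats ------------------------------------------------------------
    reg = stage("stats")
    st_path = out / "stats_summary.json"
    entry: dict = {}
    if sw.switch_time is not None:
        pre = gamma_bp.values[gamma_bp.times < sw.switch_time]
        post = gamma_bp.values[gamma_bp.times >= sw.switch_time]
        if pre.size >= 2 and post.size >= 2:
            res = stats.unpaired_ttest(pre, post)
            entry["gamma_pre_vs_post"] = {
                "t": res.statistic, "df": res.df, "p": res.p,
                "method": res.method,
                "mean_pre_uv2": float(pre.mean()),
                "mean_post_uv2": float(post.mean())}
    st_path.write_text(json.dumps(entry, indent=1))
    reg(st_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
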