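"""Mode segmentation, prevalence, switch detection, group p-traces, REM."""

import numpy as np
import pytest

from lfpipe.recio import BandDef
from lfpipe.spectral import BandPowerSeries
from lfpipe.states import (ModeFeatures, ModeSegmentation, classify_modes,
                           compute_mode_features, detect_switch,
                           group_switch_trace, mode_prevalence, rem_present)
from lfpipe.synth import MODE_PRESETS, SimulationConfig, generate_recording
from lfpipe import spectral


BAND = BandDef("g", 30.0, 140.0)


def make_features(theta, delta, broadband, speed=None, low3=None, step=3.0):
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    return ModeFeatures(times=np.arange(n) * step, theta=theta,
                        delta=np.asarray(delta, dtype=float),
                        low3=np.asarray(low3 if low3 is not None else delta,
                                        dtype=float),
                        broadband=np.asarray(broadband, dtype=float),
                        speed=None if speed is None
                        else np.asarray(speed, dtype=float))


def make_seg(labels):
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    feats = make_features(np.ones(n), np.ones(n), np.ones(n))
    return ModeSegmentation(times=np.arange(n) * 3.0, labels=labels,
                            features=feats)


class TestClassify:
    def test_two_mode_schedule_recovered(self):
        cfg = SimulationConfig(
            schedule=((MODE_PRESETS["I"], 300.0), (MODE_PRESETS["II"], 300.0)),
            seed=4)
        rec, truth = generate_recording(cfg)
        spec = spectral.multitaper_spectrogram(rec.get("ca1"), rec.fs,
                                               band=(1.0, 140.0))
        # mode I is the mobile state; synthesize the matching speed series
        speed = np.where(spec.times < 300.0, 100.0, 0.0)
        seg = classify_modes(compute_mode_features(spec, speed))
        true = truth.labels_at(spec.times)
        keep = np.abs(spec.times - 300.0) > 33.0  # exclude transition bins
        acc = np.mean(seg.labels[keep] == true[keep])
        assert acc >= 0.90

    def test_all_zero_features_unknown(self):
        feats = make_features(np.zeros(10), np.zeros(10), np.zeros(10),
                              speed=np.zeros(10))
        seg = classify_modes(feats, reference_broadband=1.0)
        assert np.all(seg.labels == "unknown")

    def test_mode_iv_requires_attenuation(self):
        # immobile, delta-dominant, broadband at 30% of reference -> IV
        feats = make_features(np.ones(10), np.full(10, 4.0), np.full(10, 0.3),
                              speed=np.zeros(10))
        seg = classify_modes(feats, reference_broadband=1.0)
        assert np.all(seg.labels == "IV")
        # same features at reference power -> II
        feats2 = make_features(np.ones(10), np.full(10, 4.0), np.ones(10),
                               speed=np.zeros(10))
        seg2 = classify_modes(feats2, reference_broadband=1.0)
        assert np.all(seg2.labels == "II")

    def test_no_speed_falls_back_to_theta_state(self):
        feats = make_features(np.full(10, 4.0), np.ones(10), np.ones(10))
        seg = classify_modes(feats, reference_broadband=1.0)
        assert np.all(seg.labels == "theta-state")

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0.5, 4.0, 40)
        delta = rng.uniform(0.5, 4.0, 40)
        bb = rng.uniform(0.2, 2.0, 40)
        speed = rng.uniform(0.0, 100.0, 40)
        a = classify_modes(make_features(theta, delta, bb, speed))
        c = 37.5
        b = classify_modes(make_features(c * theta, c * delta, c * bb, speed))
        assert np.array_equal(a.labels, b.labels)

    def test_smoothing_removes_single_bin_flicker(self):
        theta = np.ones(20)
        delta = np.full(20, 4.0)
        theta[10] = 40.0  # one spurious theta bin amidst SWS
        seg = classify_modes(make_features(theta, delta, np.ones(20),
                                           speed=np.zeros(20)),
                             reference_broadband=1.0)
        assert np.all(seg.labels == "II")


class TestPrevalence:
    def test_uniform(self):
        assert mode_prevalence(make_seg(["II"] * 10)) == {"II": 1.0}

    def test_half_half(self):
        seg = make_seg(["I"] * 5 + ["IV"] * 5)
        prev = mode_prevalence(seg)
        assert prev == {"I": 0.5, "IV": 0.5}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        seg = make_seg(rng.choice(["I", "II", "III", "IV"], 100))
        assert sum(mode_prevalence(seg).values()) == pytest.approx(1.0, abs=1e-9)

    def test_window_outside_rejected(self):
        with pytest.raises(ValueError):
            mode_prevalence(make_seg(["I"] * 5), window=(1000.0, 2000.0))

    def test_unknown_excluded(self):
        seg = make_seg(["I", "unknown", "I", "unknown"])
        assert mode_prevalence(seg) == {"I": 1.0}


def series(values, step=3.0):
    values = np.asarray(values, dtype=float)
    return BandPowerSeries(times=np.arange(values.size) * step, values=values,
                           band=BAND)


class TestDetectSwitch:
    def test_step_drop_recovered(self):
        rng = np.random.default_rng(2)
        n = 400
        vals = np.ones(n) + 0.05 * rng.standard_normal(n)
        t_drop = 200  # bin index; time 600 s at 3 s step
        vals[t_drop:] *= 0.5
        res = detect_switch(series(vals), (0.0, 300.0))
        assert res.switch_time is not None
        assert abs(res.switch_time - 600.0) <= 15.0

    def test_constant_series_no_switch(self):
        res = detect_switch(series(np.ones(200)), (0.0, 300.0))
        assert res.switch_time is None

    def test_increasing_series_no_switch(self):
        res = detect_switch(series(np.linspace(1, 3, 200)), (0.0, 300.0))
        assert res.switch_time is None

    def test_transient_dip_ignored(self):
        vals = np.ones(300)
        vals[150:155] = 0.1  # 5 bins < sustain requirement of 10
        res = detect_switch(series(vals), (0.0, 300.0))
        assert res.switch_time is None

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            detect_switch(series(np.zeros(100)), (0.0, 60.0))


class TestGroupTrace:
    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(3)
        base = [series(rng.uniform(1, 2, 50)) for _ in range(3)]
        _, t, p = group_switch_trace(base, [series(s.values.copy())
                                            for s in base])
        assert np.allclose(t, 0.0)
        assert np.allclose(p, 1.0)

    def test_large_effect_detected(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = [series(rng.normal(1.0, 0.1, 1)) for _ in range(10)]
            b = [series(rng.normal(0.5, 0.1, 1)) for _ in range(10)]
            _, _, p = group_switch_trace(a, b)
            hits += p[0] < 0.001
        assert hits >= 0.95 * n_seeds

    def test_output_length_matches_bins(self):
        rng = np.random.default_rng(4)
        a = [series(rng.uniform(1, 2, 77)) for _ in range(3)]
        b = [series(rng.uniform(1, 2, 77)) for _ in range(3)]
        times, t, p = group_switch_trace(a, b)
        assert times.size == t.size == p.size == 77

    def test_small_group_rejected(self):
        a = [series(np.ones(5))]
        b = [series(np.ones(5)), series(np.ones(5))]
        with pytest.raises(ValueError):
            group_switch_trace(a, b)


class TestRem:
    def test_long_bout_detected(self):
        seg = make_seg(["II"] * 5 + ["III"] * 10 + ["II"] * 5)
        assert rem_present(seg, min_bout_bins=3)

    def test_no_rem(self):
        assert not rem_present(make_seg(["II"] * 20), min_bout_bins=3)

    def test_short_bout_below_minimum(self):
        seg = make_seg(["II"] * 5 + ["III"] * 2 + ["II"] * 5)
        assert not rem_present(seg, min_bout_bins=3)
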