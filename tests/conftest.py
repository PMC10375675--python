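import numpy as np
import pytest

from lfpipe.synth import MODE_PRESETS, RippleParams, SimulationConfig


def overlaps(event, interval) -> bool:
    """Does a detected event (with .t_start/.t_end) overlap a (t0, t1) tuple?"""
    t0, t1 = interval
    return event.t_start < t1 and event.t_end > t0


def score_detection(events, truth_intervals):
    """(recall, precision) of detected events against ground-truth intervals."""
    if not truth_intervals:
        return None, (1.0 if not events else 0.0)
    tp = sum(1 for iv in truth_intervals if any(overlaps(e, iv) for e in events))
    recall = tp / len(truth_intervals)
    if not events:
        return recall, None
    good = sum(1 for e in events if any(overlaps(e, iv) for iv in truth_intervals))
    return recall, good / len(events)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_mode_config():
    """Short mode II -> mode IV schedule with a CA1 and an NCX channel."""
    return SimulationConfig(
        schedule=((MODE_PRESETS["II"], 60.0), (MODE_PRESETS["IV"], 60.0)),
        seed=7,
    )


@pytest.fixture
def ripple_config():
    return SimulationConfig(
        channels=(("ca1", "CA1"),),
        schedule=((MODE_PRESETS["I"], 120.0),),
        ripple_params=RippleParams(rate=12.0, amplitude_snr=10.0),
        seed=11,
    )
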