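"""Band power and spectral entropy across cortical modes.

Generates one epoch of each default mode, computes the multitaper
spectrogram, gamma band power and spectral entropy, and prints a table.
Mode IV (the inflammation-like state) should show the lowest broadband and
gamma power; spectral entropy quantifies spectral flatness independent of
amplitude.
"""

import numpy as np

from lfpipe import MODE_PRESETS, generate_mode_epoch, multitaper_spectrogram
from lfpipe.recio import BandDef
from lfpipe.spectral import band_power, spectral_entropy

FS = 1000.0
print(f"{'mode':>4} {'gamma 30-140 (uV^2)':>20} {'broadband 1-140 (uV^2)':>23} {'SpE':>6}")
for label in ("I", "II", "III", "IV"):
    rng = np.random.default_rng(0)
    x = generate_mode_epoch(MODE_PRESETS[label], 120.0, FS, rng)
    spec = multitaper_spectrogram(x, FS, window_s=30.0, step_s=3.0,
                                  band=(1.0, 140.0))
    gamma = band_power(spec, BandDef("gamma", 30.0, 140.0)).values.mean()
    broad = band_power(spec, BandDef("broadband", 1.0, 140.0)).values.mean()
    spe = spectral_entropy(spec).values.mean()
    print(f"{label:>4} {gamma:>20.1f} {broad:>23.1f} {spe:>6.3f}")
# Modes I/III are theta-dominant, II carries the large slow-wave power, and
# IV is broadband-attenuated: its gamma and broadband power fall well below
# mode II while entropy reflects how concentrated each spectrum is.
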