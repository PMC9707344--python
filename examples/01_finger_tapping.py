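"""Finger tapping: recover tapping kinematics and left-right asymmetry.

Simulates one normal and one "rubber band" recording (the band restricts one
hand's fingers, shrinking its tapping amplitude to 0.4x and slowing it to
0.6x), extracts the feature set, and prints the headline numbers.
"""

from dne import Test, gen_ft, preset
from dne.pipeline import extract_features

for label, impaired in (("normal", False), ("impaired", True)):
    rec, spec = gen_ft(preset(Test.FT, impaired=impaired, seed=7))
    fs = extract_features(rec)
    print(f"--- {label} (right {spec.freq_r:.1f} Hz/{spec.amp_r:.1f}u, "
          f"left {spec.freq_l:.1f} Hz/{spec.amp_l:.1f}u) ---")
    for name in ("ft.frequency.mean.r", "ft.frequency.mean.l",
                 "ft.amplitude.mean.r", "ft.amplitude.mean.l",
                 "ft.frequency.asym", "ft.amplitude.asym",
                 "ft.tapping_rate.r"):
        print(f"  {name:26s} {fs[name]:.3f}")

# The asymmetry metric |f_r - f_l| / (f_r + f_l) is 0 for symmetric tapping
# and approaches the analytic values Asym(2, 1.2) = 0.25 (frequency) and
# Asym(1, 0.4) = 0.43 (amplitude) under the impairment preset.
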