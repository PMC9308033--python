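"""Morse-wavelet rhythm power: ultradian band and its circadian modulation.

Transforms one male and one female temperature record with the generalized
Morse wavelet (beta=5, gamma=3), extracts the per-minute maximum power in
the ultradian band (1-3 h), then transforms that band-power series again
and extracts its circadian band (23-25 h) — the "second-order" power that
measures how strongly time of day modulates ultradian amplitude.
"""

import telemvar as tv
from telemvar.spectra import ULTRADIAN_BAND

male_spec, female_spec = tv.default_sex_profiles("temperature")

for spec, label in ((male_spec, "male"), (female_spec, "female")):
    s = tv.clean(tv.simulate_animal(spec, n_days=14, seed=7,
                                    animal_id=label, signal_kind="temperature"))
    wpm = tv.morse_cwt(s)
    ult = tv.band_power_summary(tv.band_max_power(wpm, *ULTRADIAN_BAND))
    second = tv.band_power_summary(tv.circadian_modulation_of_ultradian(s))
    print(f"{label:6s}  ultradian median power = {ult['median']:.4f}   "
          f"second-order circadian-of-ultradian median = {second['median']:.6f}")

print("\nThe male shows higher ultradian power (larger amplitude) and higher"
      "\nsecond-order power (deeper circadian modulation of that amplitude).")
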