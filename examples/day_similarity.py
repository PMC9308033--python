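"""Day-to-day self-similarity by unconstrained dynamic time warping.

For one male and one female, computes the DTW distance between each pair of
successive days (13 distances for 14 days) — the cost, in signal units, of
warping one day to best match the next — and the same distances divided by
the individual's overall SD, which separates proportional structure from
variability scale.
"""

import numpy as np

import telemvar as tv

male_spec, female_spec = tv.default_sex_profiles("temperature")

for spec, label in ((male_spec, "male"), (female_spec, "female")):
    s = tv.clean(tv.simulate_animal(spec, n_days=14, seed=3,
                                    animal_id=label, signal_kind="temperature"))
    d = tv.consecutive_day_distances(s)
    nd = tv.sd_normalized_distances(d, s)
    print(f"{label:6s}  mean day-to-day DTW distance = {d.mean():7.1f} "
          f"(degC summed along the path)  |  SD-normalized = {nd.mean():6.1f}")

print("\nThe male is farther from his own next day even after dividing by his"
      "\nown SD: less of his within-day variance is structured/re-alignable.")
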