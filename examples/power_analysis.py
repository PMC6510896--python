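"""Minimum cohort size for a target power, from pilot means and sds.

Given per-class means and standard deviations of a spectral intensity, how
many subjects per group does a two-tailed two-sample t-test need for 80%
power at alpha = 0.05?  The sizes grow at a fixed HC:patient ratio and
minimality is verified at one step smaller.
"""

import bloodspec as bs

# a hypothetical pilot: normalised intensities at one biomarker wavenumber
res = bs.power_min_n(
    mean_a=0.1456, sd_a=0.0030,   # healthy controls
    mean_b=0.1430, sd_b=0.0032,   # patients
    alpha=0.05, power_target=0.80,
    ratio=30 / 21,                # recruit ~1.4 controls per patient
)
print(f"effect size d = {res.effect_size:.2f}")
print(f"minimum cohort: {res.n_a} controls and {res.n_b} patients "
      f"(achieved power {res.achieved_power:.3f})")

# the textbook benchmark: d = 1.0, equal groups -> 17 per group
bench = bs.power_min_n(0.0, 1.0, 1.0, 1.0)
print(f"benchmark d = 1.0, equal groups: n = {bench.n_b} per group "
      f"(power {bench.achieved_power:.3f})")
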