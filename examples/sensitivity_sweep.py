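"""Bound wrist moments over the literature parameter ranges.

Sweeps PCSA, specific tension and moment arm over their published min/max
bounds and reports per-muscle and total moment envelopes per motion
direction, plus a one-at-a-time influence ranking for extension.
"""

from wristopt import (
    envelopes_frame,
    load_parameter_ranges,
    rank_parameters,
    sweep_moment,
    sweep_peak_force,
)

ranges = load_parameter_ranges()

env = sweep_peak_force(ranges, "FCR")
print(f"FCR peak force envelope: {env.min:.0f} .. {env.max:.0f} N\n")

for direction in ("flexion", "extension", "radial_dev", "ulnar_dev"):
    print(f"--- {direction} moment envelopes (N*mm) ---")
    print(envelopes_frame(sweep_moment(ranges, direction)).to_string(index=False))
    print()

print("one-at-a-time influence ranking, extension (midpoint baseline):")
print(rank_parameters(ranges, "extension").to_string(index=False))

print(
    "\nEvery output is multilinear in its inputs, so envelope extremes sit"
    "\nat range corners; 'span' ranks how much each parameter's literature"
    "\nuncertainty moves the total extension moment."
)
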