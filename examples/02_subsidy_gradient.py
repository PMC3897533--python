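"""Scan terrestrial prey subsidies from 0% to 200% of the field rate.

Donor-controlled terrestrial prey feed the predators directly, so the
subsidy gradient mainly moves predator biomass: trout intercept the
flux first and respond strongly, salamanders only receive what trout
cannot consume.  Lower trophic levels barely move.
"""

import math

from streamweb import (CalibrationSpec, ModelParams,
                       calibrate_free_parameters, build_scenarios,
                       run_scenarios, summarize)

calibration = calibrate_free_parameters(CalibrationSpec(), ModelParams())
scenarios = [s for s in build_scenarios()
             if s.trout_present and s.salamander_present
             and abs(s.armored_fraction - 0.13 / 0.23) < 1e-9]
runs = run_scenarios(scenarios, calibration.params, D_0=calibration.D_0)
table = summarize(runs).sort_values("subsidy_multiplier")

print("subsidy  day-90 trout  day-90 salamander  day-90 vulnerable")
for _, row in table.iterrows():
    print(f"  {row.subsidy_multiplier:4.0%}   {row.day90_T:12.3f}  "
          f"{row.day90_S:17.3f}  {row.day90_H:17.4f}")

t = table.set_index("subsidy_multiplier")
lrr_200 = math.log(t.loc[2.0, "day90_T"] / t.loc[0.0, "day90_T"])
print(f"\ntrout LRR, 200% vs 0% subsidy: {lrr_200:.3f} "
      f"(= {100 * (math.exp(lrr_200) - 1):.0f}% more trout biomass)")
print("Salamander gains are small: trout exhaust the subsidy before "
      "any is left over, except at the highest input rates.")
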