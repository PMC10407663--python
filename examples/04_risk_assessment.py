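"""Monte Carlo dietary risk assessment: chronic hazard quotients over the
combined four-category diet, acute per-category risks, and the
what-if effect of cutting the highest cereal residue to its legal limit.

Hazard quotients compare estimated intake (mg of residue per kg body weight
per day) with a reference dose of 0.02 mg/kg/day; values above 1 flag a
potential health concern.
"""

import warnings

from residuerisk import (GeneratorConfig, SimulationConfig, acute_risk,
                         chronic_risk, combined_exceedance_percentile,
                         default_consumption_profiles, default_specs,
                         generate_survey)
from residuerisk.io import Category, Population, EXPOSURE_CATEGORIES

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    records = generate_survey(default_specs(), GeneratorConfig(seed=1))

by_cat = {c: [r for r in records if r.category == c]
          for c in EXPOSURE_CATEGORIES}
profiles = {p.population: p for p in default_consumption_profiles()}
cfg = SimulationConfig(seed=7, n_iter=10_000)

print("chronic risk of the combined diet (10,000 iterations):")
for pop, prof in profiles.items():
    dist = chronic_risk(prof, by_cat, cfg)
    frac = dist.exceedance([0.1, 1.0])
    print(f"  {pop.value:18s} median {dist.percentiles[50.0]:.4f}  "
          f">0.1: {100 * frac[0.1]:.1f}%  >1: {100 * frac[1.0]:.2f}%")
print("fractions above the 0.1 and 1 reference lines are the shares of the "
      "simulated population exceeding those hazard levels.")

child = profiles[Population.CHILDREN_2_7]
ar = acute_risk(child, by_cat[Category.CEREAL], Category.CEREAL, cfg)
print(f"\nchild acute cereal risk: median {ar.percentiles[50.0]:.4f}, "
      f"97.5th {ar.percentiles[97.5]:.4f}, IESTI-style bound {ar.ar_upper:.4f}")
pct = combined_exceedance_percentile(0.975, 0.975, 0.025)
print(f"the IESTI-style bound sits at the {100 * pct:.4f}th percentile of "
      "the joint exposure distribution (independence assumed).")

# what-if: the highest rice residue (5.2 mg/kg) cut to its 2 mg/kg limit
from residuerisk.io import ResidueRecord, Source

def rice(conc):
    return [ResidueRecord("Rice", Category.CEREAL, "HEN", 2015,
                          Source.UNKNOWN, conc, False, 0.01, 0.01)]

d52 = acute_risk(child, rice(5.2), Category.CEREAL, cfg)
d20 = acute_risk(child, rice(2.0), Category.CEREAL, cfg)
ratio = d20.percentiles[97.5] / d52.percentiles[97.5]
print(f"\nacute risk scales exactly with concentration: a residue cut from "
      f"5.2 to 2.0 mg/kg multiplies risk by {ratio:.3f} (= 2.0/5.2); "
      f"a reported child risk of 4.6 becomes {4.6 * ratio:.1f}.")
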