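# residuerisk

Censored pesticide-residue survey statistics and probabilistic dietary
exposure/risk assessment, built for the desk layer of large food-monitoring
programs: national surveys that measure one pesticide (here, the fungicide
carbendazim and its precursors expressed as carbendazim) across tens of
thousands of samples, dozens of foods, many provinces and a decade of
collection years.

It is written for risk assessors and biostatisticians who need to

* summarize **left-censored** concentration data — samples below their
  limit of detection (LOD) are reported as "ND" and substituted at ½·LOD
  only where a numeric value is unavoidable;
* report the field's standard survey statistics: detection frequency at the
  0.01 mg kg⁻¹ limit of quantification (DF_≥0.01), the conditional median
  among quantified samples (median_≥0.01), maxima, and the over-limit ratio
  (OLR) against maximum residue limits (MRLs);
* associate residues with provincial pesticide usage and dosage
  (kg of pesticide per ton of produce) through Spearman rank correlations
  and Mann-Whitney / Kruskal-Wallis comparisons;
* run **Monte Carlo** chronic and acute hazard-quotient assessments for
  five population groups over four food categories.

## Model

Chronic risk (CR) for a population is the hazard quotient of combined daily
exposure over vegetables, fruits, cereals and potatoes,

```
CR_i = Σ_f  c_{f,i} · q_{f,i} / (w_i · ADI)
```

and acute risk (AR) is the single-category, single-day analogue

```
AR_i = c_i · q_i / (w_i · ARfD)
```

where per-iteration consumption `q` and body weight `w` are drawn from
positive normals around total-diet-study means with a 10% coefficient of
variation, concentration `c` is resampled from the ½·LOD-substituted survey
values, and ADI = ARfD = NOAEL / SF = 10/500 = 0.02 mg kg⁻¹ day⁻¹.
Simulations run 10,000 iterations by default.  An IESTI-style deterministic
upper bound combines the 97.5th percentiles of concentration and
consumption with the 2.5th percentile of body weight; under independence
that joint event sits at the 1 − (1−0.975)(1−0.975)(0.025) = 99.9984th
percentile of the exposure distribution.

Because the underlying survey records are not public, the package ships a
**calibrated synthetic-survey generator**: for each of 66 foods it draws
detected concentrations from a lognormal truncated at the quantification
limit, with parameters solved so the conditional median and the maximum
(treated as a plug-in quantile at rank (n_detect − ½)/n_detect) match the
published per-food summaries, and non-detect probabilities match the
published detection frequencies.  Every downstream statistic is validated
by parameter recovery against those targets.

## Worked example

```python
import warnings
from residuerisk import (GeneratorConfig, SimulationConfig, chronic_risk,
                         default_consumption_profiles, default_specs,
                         detection_frequency, generate_survey)
from residuerisk.io import EXPOSURE_CATEGORIES

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    records = generate_survey(default_specs(), GeneratorConfig(seed=1))
print(f"{100 * detection_frequency(records):.1f}%")   # 12.3%

by_cat = {c: [r for r in records if r.category == c]
          for c in EXPOSURE_CATEGORIES}
child = next(p for p in default_consumption_profiles()
             if p.population.value == "children_2_7")
dist = chronic_risk(child, by_cat, SimulationConfig(seed=7))
print(f"{dist.percentiles[50.0]:.4f}")                 # 0.0037
print(f"{100 * dist.exceedance([1.0])[1.0]:.2f}%")     # 0.23%
```

The first number is the overall detection frequency of the generated
survey (the emulated survey reported 12.2% across 117,289 samples); the
second is the median chronic hazard quotient for children — far below the
concern level of 1; the third is the share of the simulated child
population whose chronic quotient exceeds 1 (under 0.5%).

The `examples/` directory holds one short narrative script per capability
(survey generation, summary tables, trend association, risk assessment);
each prints the numbers it computes and one line on what they mean.  A thin
CLI mirrors the pipeline: `residuerisk simulate | summarize | trend | risk |
report | all`.

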