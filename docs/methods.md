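# Methods

## Scope and data model

The package analyzes single-analyte residue surveys of plant-based foods.
A survey is a flat table of samples, each carrying a food name, a category
(vegetable, fruit, mushroom, cereal, tea, or potato — potatoes are kept
distinct because consumption surveys report them separately from
vegetables), a province code, a collection year, a source (production or
market), and a possibly left-censored concentration.  Censoring is
structural: a non-detect row has *no* concentration, only its limit of
detection (LOD), and the schema rejects any record claiming both.  The
conventional ½·LOD substitution is a downstream statistical operation
(`summary.substitute_censored`), never applied at parse time, so the raw
censoring state survives every round trip.

## Survey summary statistics

* **Detection frequency** DF_≥t is the share of samples whose *measured*
  concentration is at or above a threshold t (default 0.01 mg kg⁻¹, the
  limit of quantification).  Censored records never count, whatever their
  LOD; a censored record with LOD > t is accepted but is still a
  non-detect.  DF is monotone non-increasing in t and invariant under
  ½·LOD substitution whenever LOD ≤ LOQ ≤ 2t.
* **Conditional median** median_≥t is the midpoint-rule median over the
  samples at or above t, and is undefined (None) when none qualify.  The
  unconditional median of a mostly-censored survey would mainly reflect the
  substitution rule, which is why the conditional version is primary.  The
  all-sample median is still reported, either on substituted values
  (default) or as None whenever a majority of the group is censored
  (`median_all_mode="nd_when_censored"`).
* **Over-limit ratio** (OLR) counts samples *strictly above* the food's
  maximum residue limit — a sample exactly at the limit is compliant,
  because the MRL is a maximum permitted level.  Foods without a legal
  limit have no OLR; in grouped summaries the denominator is the subset of
  samples whose food has a limit.

Grouped summaries (`summarize`) accept any combination of record fields and
order groups lexicographically so output files are reproducible.

## Synthetic survey generator

The record-level data behind the published survey are not deposited; only
per-food summaries are printed (sample size N, DF_≥0.01, conditional
median, maximum).  The generator treats those four numbers as a
distributional target:

* each of the N samples is an independent detect with probability
  DF_≥0.01, otherwise a non-detect carrying the food's LOD;
* detected concentrations follow a lognormal truncated to [LOQ, ∞) — the
  standard residue-distribution assumption in dietary exposure practice,
  and the two printed statistics identify exactly its two parameters;
* the printed maximum is interpreted as a plug-in quantile at rank
  (n_detect − ½)/n_detect rather than an exact sample maximum, keeping
  calibration deterministic instead of rejection-based.  Generated maxima
  therefore fluctuate around (and sometimes above) the printed value.

Calibration reduces to a one-dimensional root find on the standardized
truncation point a = (ln LOQ − μ)/σ, since the gap ratio
(ln max − ln med)/(ln med − ln LOQ) depends on a alone; μ and σ then follow
from the median constraint.  Two boundary regimes are handled explicitly:

* **Medians at the floor.**  A continuous truncated law cannot place its
  conditional median exactly at the truncation point, so foods whose
  printed median is at or below the LOQ (printed as 0.00–0.01 in the
  source table; flagged `median_floor` in the packaged fixture) calibrate
  to a point mass at max(median, LOQ).
* **Unattainable maxima.**  The gap ratio is bounded above by roughly
  log₂(1/(1−p)) − 1 as a → ∞, so a maximum several orders of magnitude
  above a median barely over the floor cannot be reached by any member of
  the family (five of the 66 packaged foods, e.g. cabbage with median
  0.02 and maximum 21).  The calibration then clamps a at 12 — the
  heaviest attainable member, asymptotically a power law above the LOQ —
  matches the conditional median exactly, undershoots the maximum, and
  emits a warning.

Randomness is keyed per (root seed, spec index), so adding a food never
perturbs another food's draws, and identical (specs, seed) produce
byte-identical survey files.  Parameter recovery is the package's central
validation: regenerating the full 117,289-record survey and summarizing by
food must return every DF within three binomial standard errors and every
conditional median inside its order-statistic confidence interval.  Because
that is a simultaneous claim over 66 foods, the per-food intervals use a
Bonferroni-corrected level (α = 0.05/66) to control the family-wise error
at 5% — uncorrected per-food 95% intervals would be expected to fail for
two or three foods by chance even under a perfect generator.

What the generator does *not* emulate: the real survey's joint
province × year structure (provinces and years are drawn independently of
concentration), between-LOD-and-LOQ values (detects start at the LOQ), any
temporal trend in the default fixture (the printed table pools years; a
spec-per-year list can express trends), and the exact shape of the upper
tail for the five clamped foods.  Passing recovery tests therefore
demonstrate that the *analysis* pipeline is correct for data with this
marginal structure, not that real residue data are lognormal.

## Trend and association layer

Pesticide dosage is usage·1000/production (kg t⁻¹).  Spearman correlations
use average ranks for ties; the two-sided p-value comes from exact
enumeration of all permutations for n ≤ 10 (small provincial comparisons
need exactness; the 10! case is vectorized in chunks) and the t
approximation above.  Two-group comparisons dispatch to the tie-corrected
Mann-Whitney U test, three or more to Kruskal-Wallis.  Annual series join
per-year survey summaries with national usage (the sum over provinces in
the usage table — a documented difference from published national totals);
years without a usage datum carry NaN, as recent usage statistics lag the
survey.

## Exposure and risk assessment

Chronic risk sums exposure over the four diet categories per iteration;
acute risk is per category.  Consumption and body weight are sampled
independently per iteration (no correlation structure is asserted) from
normals truncated to (0, ∞) by resampling — at CV 0.10 the acceptance rate
is ≈ 1, so the mean/CV intent is essentially undistorted.  Concentrations
are resampled empirically from the ½·LOD-substituted survey values by
default — assumption-free, reproducing the survey's quantiles exactly —
with a fitted-lognormal alternative.  Because empirical resampling draws
indices rather than values, scaling every concentration scales every risk
sample exactly under a fixed seed; this linearity underlies the MRL what-if
computation (cutting the highest cereal residue, 5.2 mg kg⁻¹ in rice, to
its 2 mg kg⁻¹ limit multiplies the acute risk by exactly 2/5.2, turning a
reported child risk of 4.6 into 1.8).

Seed discipline: one root seed; child streams are derived per
(population, category, parameter).  Concentration streams are keyed by
category only, i.e. shared across populations (common random numbers), so
population comparisons differ through consumption and body weight alone —
with heavy-tailed concentration sets, independent per-population draws
would otherwise swamp the age ordering in resampling noise.

Percentiles use linear interpolation between closest ranks (the numpy
default); this matters for the 97.5th concentration percentile on small
sets, which feeds the IESTI-style bound
q_conc(0.975)·q_intake(0.975)/(q_bw(0.025)·ARfD).  The intake and
body-weight quantiles in that bound are analytic truncated-normal
quantiles, and the Monte Carlo quantiles converge to them.  The combined
exceedance percentile of the bound is 1 − (1−0.975)(1−0.975)(0.025) =
0.9999844; the risk-assessment literature sometimes rounds this to a
"99.9998th percentile", which the bracketed formula does not support — the
formula is implemented as written and the discrepancy noted here rather
than reconciled.

**Known divergence on acute-risk magnitudes.**  The published acute risks
(≈ 7–12 for vegetables, 4.6 for cereals) are consistent with a
concentration percentile taken effectively at the per-food maximum, not
with the 97.5th percentile of the pooled category-wide substituted set
(which is ~0.03 mg kg⁻¹ when detection frequency is below 10%).  The
package implements the pooled-empirical default and supports a per-food
acute mode (pass a single food's records to `acute_risk`); it does not
attempt to reproduce the published magnitudes, only the exact linear
what-if relationship above.

## Default parameters

| parameter | default | why |
|---|---|---|
| threshold t | 0.01 mg kg⁻¹ | the method's limit of quantification; aligns with international reporting |
| censored substitution | ½·LOD | the survey's own footnoted convention |
| n_iter | 10,000 | the published simulation size |
| CV (intake, body weight) | 0.10 | the published variable coefficient |
| ADI = ARfD | 0.02 mg kg⁻¹ day⁻¹ | NOAEL 10 mg kg⁻¹ day⁻¹ ÷ safety factor 500 |
| OLR comparison | strict > | MRL is a maximum permitted level |
| exact-p cutoff (Spearman) | n ≤ 10 | exactness for provincial comparisons, speed for surveys |

Consumption defaults (packaged `consumption_default.csv`): the four printed
means are used verbatim (children vegetables 0.19 and cereals 0.22, adult
male vegetables 0.44 and cereals 0.45 kg day⁻¹); the remaining intakes and
the body weights (19/50/46/63/56 kg) are documented plausible values chosen
once so that intake per unit body weight declines from children through
adolescents to adults in every category — the structural feature the
acute-risk age ordering rests on.  They are placeholders for a real
total-diet-study table, which any user can substitute via
`read_consumption`.

## Numerical and degenerate-input choices

* CV = 0 returns exact copies of the mean; single-valued concentration sets
  make every Monte Carlo percentile equal the closed-form quotient exactly
  (tested as an identity, not approximately).
* Truncated-lognormal sampling works in survival space
  (z = Φ⁻¹(1 − Φ̄(a)·v)), stable for truncation points arbitrarily far into
  the tail.
* Root finds use Brent's method to xtol 1e-12; calibration reproduces both
  defining quantiles to 1e-6 relative where attainable.
* Empty record sets are errors for detection frequency and OLR (undefined
  ratios), None for conditional medians (empty conditioning set).
* File writers format floats with `repr`, so read → write → read is exact
  and outputs are byte-identical across reruns.

## Problem sizes used in validation

The test suite regenerates the full 117,289-record survey once (class-scoped
fixture) for parameter recovery, uses 10⁷ draws for the joint-percentile
Monte Carlo check, 10⁵ draws for sampler-mean convergence, 2×10⁴ iterations
for ordering/linearity properties, and 1,000 permutation replicates of
50-per-group splits for the rank-test calibration check (at 50 per group
the Mann-Whitney normal approximation contributes a Kolmogorov-Smirnov
distance of only 0.006, so the check tests the implementation rather than
the approximation).

## Limitations

* Source apportionment (PCA over high-residue samples) is out of scope; the
  observation matrix behind the published analysis is not specified.
* No processing-factor tier beyond scaling concentrations before input; no
  multi-pesticide cumulative assessment; no animal-product categories.
* The generator's province and year assignments are independent of
  concentration, so spatial-temporal analyses on generated data test
  mechanics, not geography.
* Published provincial correlation p-values (0.06, 0.08) require the full
  provincial dataset and are validated only at the property level (correct
  sign and calibration on synthetic data).
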