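import numpy as np
import pytest

from residuerisk.io import (Category, ConsumptionProfile, Population,
                            ReferenceDose, ValidationError,
                            EXPOSURE_CATEGORIES)
from residuerisk.risk import (SimulationConfig, acute_risk, chronic_risk,
                              combined_exceedance_percentile,
                              default_consumption_profiles,
                              exceedance_fractions, reference_dose_from_noael,
                              sample_concentration, sample_positive_normal)

from conftest import make_record


def profile(intakes=None, bw=60.0, cv=0.10,
            population=Population.ADULT_MALE):
    intakes = intakes or {c: 0.3 for c in EXPOSURE_CATEGORIES}
    return ConsumptionProfile(population=population, intake_mean=intakes,
                              body_weight_mean=bw, cv=cv)


def constant_records(conc, category=Category.CEREAL, n=5, **kw):
    return [make_record(conc, food="rice", category=category, **kw)
            for _ in range(n)]


class TestSamplePositiveNormal:
    def test_zero_cv_degenerate(self):
        draws = sample_positive_normal(0.22, 0.0, 50, 1)
        assert (draws == 0.22).all()

    def test_mean_recovered_within_clt_bound(self):
        n = 100_000
        draws = sample_positive_normal(1.0, 0.1, n, 12)
        assert abs(draws.mean() - 1.0) <= 3 * 0.1 / np.sqrt(n)
        assert (draws > 0).all()

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            sample_positive_normal(0.0, 0.1, 5, 1)


class TestSampleConcentration:
    def test_all_censored_degenerates_to_half_lod(self):
        recs = constant_records(None, lod=0.01, loq=0.01)
        draws = sample_concentration(recs, 100, 3)
        assert (draws == 0.005).all()

    def test_single_detect_degenerate(self):
        recs = constant_records(5.2, n=1)
        draws = sample_concentration(recs, 100, 3)
        assert (draws == 5.2).all()

    def test_resampling_frequency_binomial_bound(self):
        recs = [make_record(None, lod=0.01, loq=0.01), make_record(0.1)]
        n = 10_000
        draws = sample_concentration(recs, n, 4)
        frac = (draws == 0.1).mean()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_lognormal_model_spans_detects_and_censored(self):
        recs = [make_record(0.1), make_record(0.2), make_record(None, lod=0.01)]
        draws = sample_concentration(recs, 5000, 5, model="lognormal_fitted")
        assert (draws > 0).all()
        assert (draws == 0.005).any()  # censored mass at half LOD


class TestChronicRisk:
    def test_closed_form_single_category(self):
        # CR = q*c/(w*ADI) exactly when cv = 0 and one concentration value
        prof = profile(intakes={Category.CEREAL: 0.45}, bw=60.0, cv=0.0)
        recs = {Category.CEREAL: constant_records(0.02)}
        cfg = SimulationConfig(seed=1, n_iter=500, cv=0.0)
        dist = chronic_risk(prof, recs, cfg, categories=[Category.CEREAL])
        assert np.allclose(dist.samples, 0.0075, rtol=1e-12)
        assert all(v == pytest.approx(0.0075) for v in dist.percentiles.values())

    def test_linearity_in_concentration(self):
        prof = profile()
        cfg = SimulationConfig(seed=7, n_iter=2000)
        recs1 = {c: constant_records(0.02, category=c) + constant_records(0.5, category=c)
                 for c in EXPOSURE_CATEGORIES}
        recs2 = {c: constant_records(0.04, category=c) + constant_records(1.0, category=c)
                 for c in EXPOSURE_CATEGORIES}
        d1 = chronic_risk(prof, recs1, cfg)
        d2 = chronic_risk(prof, recs2, cfg)
        assert np.allclose(d2.samples, 2 * d1.samples, rtol=1e-12)

    def test_contributions_equal_intake_shares_under_equal_concentration(self):
        intakes = {Category.VEGETABLE: 0.4, Category.FRUIT: 0.1,
                   Category.CEREAL: 0.4, Category.POTATO: 0.1}
        prof = profile(intakes=intakes, cv=0.0)
        recs = {c: constant_records(0.05, category=c) for c in EXPOSURE_CATEGORIES}
        cfg = SimulationConfig(seed=2, n_iter=100, cv=0.0)
        dist = chronic_risk(prof, recs, cfg)
        assert sum(dist.contributions.values()) == pytest.approx(1.0, abs=1e-9)
        for c in EXPOSURE_CATEGORIES:
            assert dist.contributions[c] == pytest.approx(intakes[c])

    def test_missing_category_named(self):
        prof = profile()
        recs = {c: constant_records(0.05, category=c) for c in EXPOSURE_CATEGORIES}
        recs.pop(Category.POTATO)
        with pytest.raises(ValidationError, match="potato"):
            chronic_risk(prof, recs, SimulationConfig(seed=1, n_iter=10))


class TestAcuteRisk:
    def test_closed_form_degenerate(self):
        prof = profile(intakes={Category.CEREAL: 0.2}, bw=20.0, cv=0.0)
        recs = constant_records(2.0)
        cfg = SimulationConfig(seed=1, n_iter=200, cv=0.0)
        dist = acute_risk(prof, recs, Category.CEREAL, cfg)
        assert np.allclose(dist.samples, 1.0, rtol=1e-12)
        assert dist.ar_upper == pytest.approx(1.0)

    def test_linearity_what_if_concentration_cut_to_limit(self):
        # reducing the only concentration from 5.2 to 2.0 scales the acute
        # risk by exactly 2.0/5.2 under a fixed seed
        prof = profile(intakes={Category.CEREAL: 0.22}, bw=19.0,
                       population=Population.CHILDREN_2_7)
        cfg = SimulationConfig(seed=5, n_iter=4000)
        d_max = acute_risk(prof, constant_records(5.2), Category.CEREAL, cfg)
        d_mrl = acute_risk(prof, constant_records(2.0), Category.CEREAL, cfg)
        assert np.allclose(d_mrl.samples, d_max.samples * (2.0 / 5.2), rtol=1e-12)

    def test_age_ordering_of_mean_acute_risk(self):
        # intake per body weight declines with age, so mean AR declines from
        # children through adolescents to adults
        profiles = {p.population: p for p in default_consumption_profiles()}
        recs = [make_record(c, food="rice", category=Category.CEREAL,
                            lod=0.01, loq=0.01)
                for c in [None] * 90 + [0.02, 0.05, 0.1, 0.3, 0.5, 1.0, 2.0,
                                        3.0, 4.0, 5.2]]
        cfg = SimulationConfig(seed=11, n_iter=20_000)
        means = {pop: acute_risk(prof, recs, Category.CEREAL, cfg).samples.mean()
                 for pop, prof in profiles.items()}
        child = means[Population.CHILDREN_2_7]
        adol = (means[Population.ADOLESCENT_MALE],
                means[Population.ADOLESCENT_FEMALE])
        adult = (means[Population.ADULT_MALE], means[Population.ADULT_FEMALE])
        assert child > max(adol)
        assert min(adol) > max(adult)

    def test_upper_bound_construction_converges(self):
        # MC 97.5th percentile approaches the analytic IESTI-style inputs
        prof = profile(intakes={Category.CEREAL: 0.45}, bw=63.0)
        recs = constant_records(1.0)  # single-valued: conc quantile exact
        cfg = SimulationConfig(seed=3, n_iter=100_000)
        dist = acute_risk(prof, recs, Category.CEREAL, cfg)
        # with constant concentration the MC p97.5 reflects intake/bw spread;
        # it must land near (but below) the joint-extreme deterministic bound
        assert dist.percentiles[97.5] < dist.ar_upper
        assert dist.percentiles[97.5] > 0.5 * dist.ar_upper


class TestPercentileAlgebra:
    def test_stated_quantile_combination(self):
        v = combined_exceedance_percentile(0.975, 0.975, 0.025)
        assert v == pytest.approx(1 - 1.5625e-5, abs=1e-12)

    @pytest.mark.parametrize("args,expected", [
        ((0.0, 0.0, 1.0), 0.0),
        ((1.0, 1.0, 0.5), 1.0),
        ((1.0, 0.3, 0.9), 1.0),
    ])
    def test_boundaries(self, args, expected):
        assert combined_exceedance_percentile(*args) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            combined_exceedance_percentile(1.2, 0.5, 0.5)


class TestReferenceDose:
    @pytest.mark.parametrize("noael,sf,expected", [
        (10.0, 500.0, 0.02),
        (3.0, 1.0, 3.0),
        (0.1, 100.0, 0.001),
    ])
    def test_derivation(self, noael, sf, expected):
        ref = reference_dose_from_noael(noael, sf)
        assert ref.adi == expected and ref.arfd == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            reference_dose_from_noael(-1.0, 500.0)


class TestExceedanceFractions:
    def _dist(self, samples):
        prof = profile()
        from residuerisk.risk import RiskDistribution
        return RiskDistribution(population=prof.population, risk_type="chronic",
                                category="combined",
                                samples=np.asarray(samples, dtype=float),
                                percentiles={})

    def test_enumerated(self):
        frac = exceedance_fractions(self._dist([0.05, 0.15, 1.5, 0.2]), [0.1, 1])
        assert frac == {0.1: 0.75, 1.0: 0.25}

    def test_all_zero(self):
        assert exceedance_fractions(self._dist([0.0, 0.0]), [0.1]) == {0.1: 0.0}

    def test_threshold_below_minimum(self):
        assert exceedance_fractions(self._dist([1.0, 2.0]), [0.5]) == {0.5: 1.0}


def test_default_profiles_structure():
    profiles = default_consumption_profiles()
    assert {p.population for p in profiles} == set(Population)
    by_pop = {p.population: p for p in profiles}
    child = by_pop[Population.CHILDREN_2_7]
    assert child.intake_mean[Category.VEGETABLE] == 0.19
    assert child.intake_mean[Category.CEREAL] == 0.22
    adult = by_pop[Population.ADULT_MALE]
    assert adult.intake_mean[Category.VEGETABLE] == 0.44
    assert adult.intake_mean[Category.CEREAL] == 0.45
    # structural TDS feature: intake per body weight declines with age
    for cat in EXPOSURE_CATEGORIES:
        ratios = [by_pop[p].intake_mean[cat] / by_pop[p].body_weight_mean
                  for p in (Population.CHILDREN_2_7, Population.ADOLESCENT_MALE,
                            Population.ADULT_MALE)]
        assert ratios[0] > ratios[1] > ratios[2]
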