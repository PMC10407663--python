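import numpy as np
import pytest
from scipy.stats import norm

from residuerisk.io import Category
from residuerisk.synthetic import (CalibrationError, FoodResidueSpec,
                                   GeneratorConfig, calibrate_lognormal,
                                   default_mrl_table, default_specs,
                                   generate_survey, read_specs, write_specs)
from residuerisk.io import write_survey


def truncated_quantile(mu, sigma, loq, p):
    """Independent evaluation of the [loq, inf)-truncated lognormal quantile."""
    if sigma == 0:
        return float(np.exp(mu))
    a = (np.log(loq) - mu) / sigma
    z = norm.isf(norm.sf(a) * (1 - p))
    return float(np.exp(mu + sigma * z))


def grid_search_calibration(median_above, max_conc, n_detect, loq):
    """Brute-force oracle: scan sigma, solve mu from the median constraint by
    bisection, return the pair minimizing the max-quantile error."""
    p = (n_detect - 0.5) / n_detect
    best = None
    for sigma in np.geomspace(1e-3, 20, 4000):
        lo, hi = np.log(1e-12), np.log(median_above)  # truncated median > e^mu
        for _ in range(200):
            mu = 0.5 * (lo + hi)
            med = truncated_quantile(mu, sigma, loq, 0.5)
            if med < median_above:
                lo = mu
            else:
                hi = mu
        mu = 0.5 * (lo + hi)
        err = abs(truncated_quantile(mu, sigma, loq, p) - max_conc)
        if best is None or err < best[0]:
            best = (err, mu, sigma)
    return best[1], best[2]


class TestCalibrateLognormal:
    def test_degenerate_point_mass(self):
        mu, sigma = calibrate_lognormal(0.05, 0.05, 17, 0.01)
        assert sigma == 0.0
        assert mu == pytest.approx(np.log(0.05))

    def test_two_quantile_constraints_reproduced(self):
        # heavy-tailed stone-fruit-like food: median 0.05, max 8.39, 1255 detects
        mu, sigma = calibrate_lognormal(0.05, 8.39, 1255, 0.01)
        p = (1255 - 0.5) / 1255
        assert truncated_quantile(mu, sigma, 0.01, 0.5) == pytest.approx(0.05, rel=1e-6)
        assert truncated_quantile(mu, sigma, 0.01, p) == pytest.approx(8.39, rel=1e-6)

    def test_matches_grid_search_oracle(self):
        mu, sigma = calibrate_lognormal(0.05, 8.39, 1255, 0.01)
        mu_g, sigma_g = grid_search_calibration(0.05, 8.39, 1255, 0.01)
        assert sigma == pytest.approx(sigma_g, rel=2e-3)
        assert mu == pytest.approx(mu_g, rel=2e-3)

    def test_extreme_leafy_vegetable_median(self):
        # spinach-like: conditional median 0.11, maximum 110
        n_detect = round(1864 * 0.072)
        mu, sigma = calibrate_lognormal(0.11, 110.0, n_detect, 0.01)
        assert truncated_quantile(mu, sigma, 0.01, 0.5) == pytest.approx(0.11, rel=1e-6)

    def test_max_below_median_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_lognormal(0.5, 0.1, 10, 0.01)

    def test_unattainable_tail_clamps_with_warning(self):
        # max several orders above a median barely over the floor: the
        # truncated-lognormal family cannot reach it at this rank
        with pytest.warns(UserWarning, match="unattainable"):
            mu, sigma = calibrate_lognormal(0.02, 21.0, 40, 0.01)
        # the median constraint still holds exactly
        assert truncated_quantile(mu, sigma, 0.01, 0.5) == pytest.approx(0.02, rel=1e-6)

    def test_median_at_floor_degenerates_to_point_mass(self):
        mu, sigma = calibrate_lognormal(0.01, 0.02, 6, 0.01)
        assert sigma == 0.0


class TestGenerateSurvey:
    def spec(self, **kw):
        base = dict(food="tomato", category=Category.VEGETABLE, n=100,
                    df_target=0.2, median_above=0.03, max_conc=2.46, lod=0.001)
        base.update(kw)
        return FoodResidueSpec(**base)

    def test_zero_detection_frequency_all_censored(self):
        recs = generate_survey([self.spec(df_target=0.0, n=50)],
                               GeneratorConfig(seed=5))
        assert len(recs) == 50
        assert all(r.censored for r in recs)

    def test_degenerate_distribution_all_at_median(self):
        recs = generate_survey([self.spec(df_target=1.0, median_above=0.03,
                                          max_conc=0.03)],
                               GeneratorConfig(seed=5))
        assert all(r.concentration == 0.03 for r in recs)

    def test_detect_fraction_within_binomial_bound(self):
        # large-crop-like: n=4250, df 13.7%
        spec = self.spec(n=4250, df_target=0.137)
        recs = generate_survey([spec], GeneratorConfig(seed=1))
        frac = sum(not r.censored for r in recs) / len(recs)
        se = np.sqrt(0.137 * (1 - 0.137) / 4250)
        assert abs(frac - 0.137) <= 3 * se

    def test_no_detect_below_loq_no_censored_concentration(self):
        recs = generate_survey([self.spec(n=2000, df_target=0.5)],
                               GeneratorConfig(seed=9))
        for r in recs:
            if r.censored:
                assert r.concentration is None
            else:
                assert r.concentration >= r.loq

    def test_deterministic_byte_identical_files(self, tmp_path):
        specs = [self.spec(), self.spec(food="rice", category=Category.CEREAL,
                                        n=50, df_target=0.022,
                                        median_above=0.02, max_conc=5.2,
                                        lod=0.01)]
        for name in ("a.csv", "b.csv"):
            recs = generate_survey(specs, GeneratorConfig(seed=11))
            write_survey(recs, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_per_spec_streams_independent(self):
        one = generate_survey([self.spec(n=30)], GeneratorConfig(seed=3))
        two = generate_survey([self.spec(n=30),
                               self.spec(food="pear", category=Category.FRUIT)],
                              GeneratorConfig(seed=3))
        assert two[:30] == one  # adding a spec does not perturb the first

    def test_province_weights_respected(self):
        spec = self.spec(n=500, province_weights={"SD": 0.5, "HEN": 0.5})
        recs = generate_survey([spec], GeneratorConfig(seed=2))
        assert {r.province for r in recs} == {"SD", "HEN"}


class TestDefaultSpecs:
    def test_cardinality_and_total_sample_count(self):
        specs = default_specs()
        assert len(specs) == 66
        assert sum(s.n for s in specs) == 117_289

    @pytest.mark.parametrize("food,n,df,maxc", [
        ("Rice", 498, 0.022, 5.20),
        ("Tea", 470, 0.009, 0.04),
        ("Spinach", 1864, 0.072, 110.0),
    ])
    def test_transcribed_entries(self, food, n, df, maxc):
        spec = {s.food: s for s in default_specs()}[food]
        assert spec.n == n
        assert spec.df_target == pytest.approx(df)
        assert spec.max_conc == maxc

    def test_median_floor_applied(self):
        by_food = {s.food: s for s in default_specs()}
        # printed conditional median below the quantification limit is floored
        assert by_food["Bayberry"].median_above == by_food["Bayberry"].loq

    def test_mrl_table_companion(self):
        mrls = {e.food: e.mrl for e in default_mrl_table()}
        assert mrls["Rice"] == 2.0
        assert mrls["Water chestnut"] is None


def test_specs_round_trip(tmp_path):
    specs = default_specs()[:5]
    path = tmp_path / "specs.csv"
    write_specs(specs, path)
    assert read_specs(path) == specs
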