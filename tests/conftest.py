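import numpy as np
import pytest
from scipy.stats import binom

from residuerisk.io import Category, ResidueRecord, Source


def make_record(conc, *, food="spinach", category=Category.VEGETABLE,
                province="SD", year=2014, source=Source.MARKET,
                lod=0.001, loq=0.01):
    """Record shorthand: conc=None means a non-detect."""
    return ResidueRecord(food=food, category=category, province=province,
                         year=year, source=source,
                         concentration=conc, censored=conc is None,
                         lod=lod, loq=loq)


def median_order_stat_ci(values, alpha=0.05):
    """Conservative order-statistic confidence interval for the population
    median: [X_(l), X_(u)] with P(#below-median < l) <= alpha/2 and
    P(#below-median > u) <= alpha/2."""
    vals = sorted(values)
    k = len(vals)
    l = int(binom.ppf(alpha / 2, k, 0.5))
    u = int(binom.isf(alpha / 2, k, 0.5))
    lo = -np.inf if l == 0 else vals[l - 1]
    hi = np.inf if u >= k else vals[u]
    return lo, hi


@pytest.fixture
def mixed_records():
    """Eight samples: {0.005, 0.01, 0.02, ND, 2.0, 0.009, ND, 0.3} —
    four at or above 0.01 by hand count."""
    concs = [0.005, 0.01, 0.02, None, 2.0, 0.009, None, 0.3]
    return [make_record(c) for c in concs]


@pytest.fixture
def survey_file(tmp_path):
    path = tmp_path / "survey.csv"
    path.write_text(
        "food,category,province,year,source,concentration,censored,lod,loq\n"
        "spinach,vegetable,SD,2014,market,110,,0.001,0.01\n"
        "spinach,vegetable,SD,2014,market,ND,,0.001,0.01\n"
        "rice,cereal,HEN,2015,production,5.2,false,0.01,0.01\n"
        "tea,tea,ZJ,2016,market,,true,0.001,0.01\n"
        "apple,fruit,SD,2017,unknown,0.04,false,0.001,0.01\n",
        encoding="utf-8")
    return path
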