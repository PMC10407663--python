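"""Synthetic residue-survey generator.

The national survey this package analyzes is summarized food-by-food
(sample count, detection frequency at the 0.01 mg kg^-1 quantification
limit, conditional median above that limit, maximum) but the underlying
records are not public.  This module generates record-level surveys whose
summaries reproduce those targets, so every downstream stage can be
exercised and validated by parameter recovery.

Detected concentrations are modeled as a lognormal truncated to
[LOQ, inf) — the standard residue-distribution assumption in dietary
exposure work, and the two printed statistics (conditional median, maximum)
identify exactly its two parameters.  The maximum is treated as a plug-in
quantile at rank (n_detect - 0.5)/n_detect so that calibration is
deterministic rather than rejection-based.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .io import Category, ResidueRecord, Source, MRLEntry, ValidationError

__all__ = [
    "FoodResidueSpec", "GeneratorConfig", "CalibrationError",
    "calibrate_lognormal", "generate_survey", "default_specs",
    "default_mrl_table", "read_specs", "write_specs", "PROVINCES",
]

#: Provincial-level division codes used when a spec gives no weights.
PROVINCES = (
    "BJ", "TJ", "HEB", "SX", "NM", "LN", "JL", "HLJ", "SH", "JS", "ZJ",
    "AH", "FJ", "JX", "SD", "HEN", "HUB", "HUN", "GD", "GX", "HN", "CQ",
    "SC", "GZ", "YN", "XZ", "SAX", "GS", "QH", "NX", "XJ",
)

#: Largest standardized truncation point used by the calibration; beyond
#: this the truncated lognormal is numerically indistinguishable from its
#: heavy-tail (log-Pareto) limit.
_A_MAX = 12.0


class CalibrationError(ValueError):
    """The two summary statistics admit no truncated-lognormal solution."""


@dataclass(frozen=True)
class FoodResidueSpec:
    """Generator target for one food: the summary its draws must reproduce."""

    food: str
    category: Category
    n: int
    df_target: float            # fraction of samples >= loq
    median_above: float         # target conditional median (mg kg^-1)
    max_conc: float             # target maximum (mg kg^-1)
    lod: float
    loq: float = 0.01
    province_weights: Mapping[str, float] | None = None
    year_range: tuple[int, int] = (2011, 2020)

    def __post_init__(self) -> None:
        if not (0 <= self.df_target <= 1):
            raise ValidationError(f"df_target out of [0,1]: {self.df_target}")
        if self.n < 0:
            raise ValidationError("n must be non-negative")
        if self.df_target > 0 and not (self.loq <= self.median_above <= self.max_conc):
            raise ValidationError(
                f"{self.food}: need loq <= median_above <= max_conc, got "
                f"({self.loq}, {self.median_above}, {self.max_conc})")
        if self.province_weights is not None:
            total = sum(self.province_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"province weights sum to {total}, not 1")

    @property
    def n_detect(self) -> int:
        """Expected detect count used as the plug-in rank for the maximum."""
        return max(1, round(self.n * self.df_target)) if self.df_target > 0 else 0


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    detect_distribution: str = "lognormal_truncated"
    censored_value_model: str = "uniform_below_lod"
    # censored_value_model describes the latent below-LOD value only; it has
    # no observable effect because censored records never carry a
    # concentration (schema invariant).


def _z_median(a: float) -> float:
    # z such that the truncated-normal CDF at z is 1/2, in survival space
    # for stability far into the tail
    return norm.isf(norm.sf(a) / 2.0)


def _z_quantile(a: float, p: float) -> float:
    return norm.isf(norm.sf(a) * (1.0 - p))


def calibrate_lognormal(median_above: float, max_conc: float, n_detect: int,
                        loq: float) -> tuple[float, float]:
    """Fit (mu, sigma) of a lognormal truncated to [loq, inf).

    Constraints: the truncated median equals ``median_above`` and the
    truncated quantile at rank (n_detect - 0.5)/n_detect equals
    ``max_conc``.  Solved by root-finding on the standardized truncation
    point a = (ln loq - mu)/sigma, which reduces the system to one
    dimension:

        (ln M - ln m) / (ln m - ln L) = (z_p(a) - z_med(a)) / (z_med(a) - a)

    where z_med and z_p are truncated-normal median and p-quantile points.

    Degenerate and boundary cases:
      * max_conc == median_above: point mass, sigma = 0;
      * median_above <= loq (printed medians at or below the quantification
        limit): a continuous truncated law cannot put its conditional median
        on the truncation floor, so a point mass at max(median_above, loq)
        is returned;
      * the ratio above exceeds its supremum over a (very heavy observed
        tails): the truncation point is clamped at a = 12 — the heaviest
        attainable member, which still matches the median exactly — and a
        warning is emitted because the maximum will be undershot.
    """
    if max_conc < median_above:
        raise CalibrationError(
            f"max ({max_conc}) below conditional median ({median_above})")
    if n_detect < 1:
        raise CalibrationError("n_detect must be >= 1")
    if median_above <= loq:
        return float(np.log(max(median_above, loq))), 0.0
    if max_conc == median_above:
        return float(np.log(median_above)), 0.0

    p = (n_detect - 0.5) / n_detect
    ratio = (np.log(max_conc) - np.log(median_above)) / \
            (np.log(median_above) - np.log(loq))

    def g(a: float) -> float:
        zm = _z_median(a)
        zp = _z_quantile(a, p)
        return (zp - zm) / (zm - a)

    a_lo = -30.0
    if g(_A_MAX) <= ratio:
        warnings.warn(
            f"maximum {max_conc} unattainable at rank {p:.6f} for median "
            f"{median_above} above loq {loq}; clamping truncation point "
            "(median matched exactly, maximum undershot)",
            stacklevel=2)
        a = _A_MAX
    else:
        a = optimize.brentq(lambda x: g(x) - ratio, a_lo, _A_MAX,
                            xtol=1e-12, rtol=1e-15)
    zm = _z_median(a)
    sigma = (np.log(median_above) - np.log(loq)) / (zm - a)
    mu = np.log(loq) - sigma * a
    return float(mu), float(sigma)


def _spec_rng(seed: int, index: int) -> np.random.Generator:
    # stable per-spec stream: independent of how many specs precede it
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _draw_detects(spec: FoodResidueSpec, k: int,
                  rng: np.random.Generator) -> np.ndarray:
    mu, sigma = calibrate_lognormal(spec.median_above, spec.max_conc,
                                    spec.n_detect, spec.loq)
    if sigma == 0.0:
        # exact point mass at the target (exp(log(m)) would perturb the
        # last ulp and break exact-median recovery)
        return np.full(k, max(spec.median_above, spec.loq))
    a = (np.log(spec.loq) - mu) / sigma
    # sample the conditional upper tail in survival space (stable for any a)
    v = rng.uniform(size=k)
    z = norm.isf(norm.sf(a) * v)
    return np.exp(mu + sigma * z)


def generate_survey(specs: Sequence[FoodResidueSpec],
                    config: GeneratorConfig) -> list[ResidueRecord]:
    """Generate one record-level survey.

    Each of a spec's ``n`` records is a detect with probability
    ``df_target`` (concentration drawn from the calibrated truncated
    lognormal, never below the LOQ) and otherwise a non-detect carrying the
    spec's LOD.  Provinces and years follow the spec's weights.  Output is
    deterministic under a fixed seed and independent across specs (adding a
    spec never perturbs another's draws).
    """
    if not specs:
        raise ValidationError("specs must be non-empty")
    if config.detect_distribution != "lognormal_truncated":
        raise ValidationError(
            f"unknown detect_distribution: {config.detect_distribution}")
    records: list[ResidueRecord] = []
    for idx, spec in enumerate(specs):
        rng = _spec_rng(config.seed, idx)
        detect = rng.uniform(size=spec.n) < spec.df_target
        k = int(detect.sum())
        concs = _draw_detects(spec, k, rng) if k else np.empty(0)
        if spec.province_weights is None:
            provinces = rng.choice(PROVINCES, size=spec.n)
        else:
            keys = sorted(spec.province_weights)
            w = np.array([spec.province_weights[key] for key in keys])
            provinces = rng.choice(keys, size=spec.n, p=w / w.sum())
        years = rng.integers(spec.year_range[0], spec.year_range[1] + 1,
                             size=spec.n)
        j = 0
        for i in range(spec.n):
            if detect[i]:
                conc, cens = float(concs[j]), False
                j += 1
            else:
                conc, cens = None, True
            records.append(ResidueRecord(
                food=spec.food, category=spec.category,
                province=str(provinces[i]), year=int(years[i]),
                source=Source.UNKNOWN, concentration=conc, censored=cens,
                lod=spec.lod, loq=spec.loq))
    return records


# ---------------------------------------------------------------------------
# packaged calibration fixture (66-food national survey summary)
# ---------------------------------------------------------------------------

SPEC_COLUMNS = ["food", "category", "n", "df_pct", "median_above", "max_conc",
                "lod", "loq"]


def _fixture_rows() -> list[dict]:
    with resources.files("residuerisk").joinpath("data/national_survey_specs.csv") \
            .open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def default_specs() -> list[FoodResidueSpec]:
    """The packaged 66-food fixture transcribing the national survey's
    printed per-food summaries (sample size, detection frequency at
    0.01 mg kg^-1, conditional median, maximum), with uniform province
    weights and the 2011-2020 year range.

    Foods flagged ``median_floor`` print a conditional median at or below
    the quantification limit; their calibration target is floored at the
    LOQ (the generator then emits a point mass there).
    """
    specs = []
    for row in _fixture_rows():
        loq = float(row["loq"])
        median = max(float(row["median_above"]), loq)
        specs.append(FoodResidueSpec(
            food=row["food"], category=Category.parse(row["category"]),
            n=int(row["n"]), df_target=float(row["df_pct"]) / 100.0,
            median_above=median,
            max_conc=max(float(row["max_conc"]), median),
            lod=float(row["lod"]), loq=loq))
    return specs


def default_mrl_table() -> list[MRLEntry]:
    """MRLs for the 66 packaged foods ('' / '-' = no limit exists)."""
    entries = []
    for row in _fixture_rows():
        tok = (row.get("mrl") or "").strip()
        entries.append(MRLEntry(
            food=row["food"], mrl=None if tok in ("", "-") else float(tok),
            authority=(row.get("authority") or "national_standard").strip()
            or "national_standard"))
    return entries


def read_specs(path: str | Path) -> list[FoodResidueSpec]:
    """Read generator specs from a delimited file (columns mirror
    :class:`FoodResidueSpec`; df given in percent)."""
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.DictReader(fh))
    specs = []
    for row in rows:
        loq = float(row.get("loq") or 0.01)
        median = max(float(row["median_above"]), loq)
        specs.append(FoodResidueSpec(
            food=row["food"], category=Category.parse(row["category"]),
            n=int(row["n"]), df_target=float(row["df_pct"]) / 100.0,
            median_above=median, max_conc=max(float(row["max_conc"]), median),
            lod=float(row["lod"]), loq=loq))
    return specs


def write_specs(specs: Iterable[FoodResidueSpec], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(SPEC_COLUMNS)
        for s in specs:
            w.writerow([s.food, s.category.value, s.n, repr(s.df_target * 100),
                        repr(s.median_above), repr(s.max_conc), repr(s.lod),
                        repr(s.loq)])
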