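"""Tabular I/O and shared domain types for residue-survey analysis.

All survey artifacts are plain delimited text (comma or tab, UTF-8, header
mandatory).  Concentrations are stored exactly as reported by the laboratory:
a non-detect ("ND") row carries *no* concentration, only its limit of
detection — the conventional ½·LOD substitution is a downstream statistical
operation, never applied at parse time, so raw censoring is preserved on disk
and in memory.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class SchemaError(ValueError):
    """A file's header does not match the documented schema."""


class ValidationError(ValueError):
    """A row or field violates a domain invariant."""


class Category(str, enum.Enum):
    """Food category; potatoes are deliberately distinct from vegetables
    because consumption surveys report them separately."""

    VEGETABLE = "vegetable"
    FRUIT = "fruit"
    MUSHROOM = "mushroom"
    CEREAL = "cereal"
    TEA = "tea"
    POTATO = "potato"

    @classmethod
    def parse(cls, token: str) -> "Category":
        t = token.strip().lower()
        # accept the plural forms used by consumption tables
        t = {"vegetables": "vegetable", "fruits": "fruit", "mushrooms": "mushroom",
             "cereals": "cereal", "potatoes": "potato", "teas": "tea"}.get(t, t)
        try:
            return cls(t)
        except ValueError:
            raise ValidationError(f"unknown category token: {token!r}") from None


class Source(str, enum.Enum):
    PRODUCTION = "production"
    MARKET = "market"
    UNKNOWN = "unknown"


class Population(str, enum.Enum):
    CHILDREN_2_7 = "children_2_7"
    ADOLESCENT_MALE = "adolescent_male"
    ADOLESCENT_FEMALE = "adolescent_female"
    ADULT_MALE = "adult_male"
    ADULT_FEMALE = "adult_female"


#: The four food categories entering the dietary exposure assessment.
EXPOSURE_CATEGORIES = (Category.VEGETABLE, Category.FRUIT, Category.CEREAL,
                       Category.POTATO)

#: ND token accepted (case-insensitively) in the concentration column.
ND_TOKEN = "ND"


@dataclass(frozen=True)
class ResidueRecord:
    """One analyzed sample with a possibly left-censored concentration.

    ``censored`` is true iff the measurement fell below the limit of
    detection; such records carry no concentration at all.
    """

    food: str
    category: Category
    province: str
    year: int
    source: Source
    concentration: float | None  # mg kg^-1; None iff censored
    censored: bool
    lod: float  # mg kg^-1
    loq: float  # mg kg^-1

    def __post_init__(self) -> None:
        if self.censored != (self.concentration is None):
            raise ValidationError(
                "censored flag must match absence of concentration "
                f"(censored={self.censored}, concentration={self.concentration})")
        if self.concentration is not None and self.concentration < 0:
            raise ValidationError(f"negative concentration: {self.concentration}")
        if self.lod <= 0 or self.loq <= 0:
            raise ValidationError("lod and loq must be positive")
        if self.lod > self.loq:
            raise ValidationError(f"lod ({self.lod}) must not exceed loq ({self.loq})")


@dataclass(frozen=True)
class MRLEntry:
    """Maximum residue limit for one food; ``mrl`` is None when no legal
    limit exists (such foods are excluded from over-limit ratios)."""

    food: str
    mrl: float | None
    authority: str = "national_standard"

    def __post_init__(self) -> None:
        if self.mrl is not None and self.mrl <= 0:
            raise ValidationError(f"mrl must be positive when present: {self.mrl}")


@dataclass(frozen=True)
class ConsumptionProfile:
    """A population group's mean daily intake per food category (kg day^-1)
    and mean body weight (kg), with a shared coefficient of variation used
    by the Monte Carlo sampler."""

    population: Population
    intake_mean: Mapping[Category, float]
    body_weight_mean: float
    cv: float = 0.10

    def __post_init__(self) -> None:
        if self.body_weight_mean <= 0:
            raise ValidationError("body weight must be positive")
        for cat, v in self.intake_mean.items():
            if v <= 0:
                raise ValidationError(f"intake mean for {cat} must be positive")
        if not (0 <= self.cv < 1):
            raise ValidationError(f"cv must be in [0, 1): {self.cv}")


@dataclass(frozen=True)
class ReferenceDose:
    """Chronic (ADI) and acute (ARfD) reference doses, mg kg^-1 day^-1.

    When derived from animal toxicity data, both equal NOAEL / safety factor.
    """

    adi: float
    arfd: float
    noael: float | None = None
    safety_factor: float | None = None

    def __post_init__(self) -> None:
        if self.adi <= 0 or self.arfd <= 0:
            raise ValidationError("reference doses must be positive")
        if self.noael is not None and self.safety_factor is not None:
            derived = self.noael / self.safety_factor
            if abs(derived - self.adi) > 1e-12 * max(1.0, derived) or \
               abs(derived - self.arfd) > 1e-12 * max(1.0, derived):
                raise ValidationError(
                    "adi and arfd must equal noael / safety_factor when both are given")


@dataclass(frozen=True)
class UsageRecord:
    """Provincial annual pesticide usage (t yr^-1) and, when available,
    agricultural production (t yr^-1) for the dosage ratio."""

    province: str
    year: int
    pesticide_usage: float
    agricultural_production: float | None = None

    def __post_init__(self) -> None:
        if self.pesticide_usage < 0:
            raise ValidationError("pesticide usage must be non-negative")
        if self.agricultural_production is not None and self.agricultural_production <= 0:
            raise ValidationError("agricultural production must be positive when present")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

SURVEY_COLUMNS = ["food", "category", "province", "year", "source",
                  "concentration", "censored", "lod", "loq"]
MRL_COLUMNS = ["food", "mrl", "authority"]
CONSUMPTION_COLUMNS = ["population", "category", "intake_mean_kg_day",
                       "body_weight_kg", "cv"]
USAGE_COLUMNS = ["province", "year", "pesticide_usage_t", "production_t"]


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _open_reader(path: str | Path, required: Sequence[str]):
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first:
            return [], []
        delim = _sniff_delimiter(first)
        header = [h.strip() for h in first.rstrip("\r\n").split(delim)]
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        rows = list(csv.DictReader(fh, fieldnames=header, delimiter=delim))
    return header, rows


def _parse_float(token: str, *, what: str, row: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"row {row}: malformed numeric {what}: {token!r}") from None


def read_survey(path: str | Path, dialect: Mapping[str, str] | None = None
                ) -> list[ResidueRecord]:
    """Read a residue survey file into validated records.

    Censoring is encoded either by the ND token (case-insensitive) in the
    concentration column or by an empty concentration with a true ``censored``
    flag.  Malformed numerics are rejected with the offending row number,
    never silently coerced.
    """
    _, rows = _open_reader(path, SURVEY_COLUMNS)
    records: list[ResidueRecord] = []
    for i, row in enumerate(rows, start=2):  # 1-based, header is line 1
        conc_token = (row.get("concentration") or "").strip()
        flag_token = (row.get("censored") or "").strip().lower()
        is_nd = conc_token.upper() == ND_TOKEN or conc_token == ""
        if flag_token in ("true", "1", "yes"):
            if not is_nd:
                raise ValidationError(
                    f"row {i}: censored flag set but concentration present")
            is_nd = True
        elif flag_token in ("false", "0", "no") and is_nd and conc_token == "":
            raise ValidationError(f"row {i}: concentration missing on uncensored row")
        conc = None if is_nd else _parse_float(conc_token, what="concentration", row=i)
        if conc is not None and conc < 0:
            raise ValidationError(f"row {i}: negative concentration {conc}")
        try:
            rec = ResidueRecord(
                food=row["food"].strip(),
                category=Category.parse(row["category"]),
                province=row["province"].strip(),
                year=int(_parse_float(row["year"], what="year", row=i)),
                source=Source((row.get("source") or "unknown").strip().lower() or "unknown"),
                concentration=conc,
                censored=is_nd,
                lod=_parse_float(row["lod"], what="lod", row=i),
                loq=_parse_float(row["loq"], what="loq", row=i),
            )
        except ValueError as exc:
            if isinstance(exc, (ValidationError, SchemaError)):
                raise
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def write_survey(records: Iterable[ResidueRecord], path: str | Path) -> None:
    """Write records in the canonical comma dialect; bit-identical output
    for identical inputs (floats via ``repr`` round-trip exactly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(SURVEY_COLUMNS)
        for r in records:
            w.writerow([
                r.food, r.category.value, r.province, r.year, r.source.value,
                ND_TOKEN if r.censored else _fmt(r.concentration),
                str(r.censored).lower(), _fmt(r.lod), _fmt(r.loq),
            ])


def read_mrl_table(path: str | Path) -> list[MRLEntry]:
    """Read an MRL table; blank/'-' limits mean no limit exists.  Duplicate
    food names are ambiguous and rejected."""
    _, rows = _open_reader(path, ["food", "mrl"])
    entries: list[MRLEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        food = row["food"].strip()
        if food in seen:
            raise ValidationError(f"row {i}: duplicate MRL entry for {food!r}")
        seen.add(food)
        tok = (row.get("mrl") or "").strip()
        mrl = None if tok in ("", "-") else _parse_float(tok, what="mrl", row=i)
        entries.append(MRLEntry(food=food, mrl=mrl,
                                authority=(row.get("authority") or "national_standard").strip()
                                or "national_standard"))
    return entries


def write_mrl_table(entries: Iterable[MRLEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(MRL_COLUMNS)
        for e in entries:
            w.writerow([e.food, _fmt(e.mrl), e.authority])


def read_consumption(path: str | Path) -> list[ConsumptionProfile]:
    """Read consumption/body-weight profiles (one row per population ×
    category).  All five population groups must be present; the coefficient
    of variation defaults to 0.10 when the column is blank."""
    _, rows = _open_reader(path, ["population", "category", "intake_mean_kg_day",
                                  "body_weight_kg"])
    by_pop: dict[Population, dict] = {}
    for i, row in enumerate(rows, start=2):
        try:
            pop = Population(row["population"].strip().lower())
        except ValueError:
            raise ValidationError(f"row {i}: unknown population "
                                  f"{row['population']!r}") from None
        cat = Category.parse(row["category"])
        d = by_pop.setdefault(pop, {"intake": {}, "bw": None, "cv": None})
        d["intake"][cat] = _parse_float(row["intake_mean_kg_day"],
                                        what="intake_mean_kg_day", row=i)
        d["bw"] = _parse_float(row["body_weight_kg"], what="body_weight_kg", row=i)
        cv_tok = (row.get("cv") or "").strip()
        if cv_tok:
            d["cv"] = _parse_float(cv_tok, what="cv", row=i)
    missing = [p.value for p in Population if p not in by_pop]
    if missing:
        raise ValidationError("missing population group(s): " + ", ".join(missing))
    return [ConsumptionProfile(population=pop,
                               intake_mean=dict(d["intake"]),
                               body_weight_mean=d["bw"],
                               cv=0.10 if d["cv"] is None else d["cv"])
            for pop, d in sorted(by_pop.items(), key=lambda kv: kv[0].value)]


def read_usage(path: str | Path) -> list[UsageRecord]:
    _, rows = _open_reader(path, ["province", "year", "pesticide_usage_t"])
    out = []
    for i, row in enumerate(rows, start=2):
        tok = (row.get("production_t") or "").strip()
        out.append(UsageRecord(
            province=row["province"].strip(),
            year=int(_parse_float(row["year"], what="year", row=i)),
            pesticide_usage=_parse_float(row["pesticide_usage_t"],
                                         what="pesticide_usage_t", row=i),
            agricultural_production=None if tok in ("", "-") else
            _parse_float(tok, what="production_t", row=i),
        ))
    return out


def write_usage(records: Iterable[UsageRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(USAGE_COLUMNS)
        for r in records:
            w.writerow([r.province, r.year, _fmt(r.pesticide_usage),
                        _fmt(r.agricultural_production)])
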