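"""Censored-survey summary statistics.

The survey's concentrations are left-censored at food-specific detection
limits.  The reporting conventions implemented here:

* non-detects are substituted at half the limit of detection (½·LOD) where
  a numeric value is unavoidable;
* the detection frequency DF_≥t counts detects at or above a threshold
  (default 0.01 mg kg^-1, the quantification limit) over all samples —
  censored records never count as detections;
* the conditional median median_≥t is taken only over samples at or above
  the threshold, because overall detection frequencies are low and an
  unconditional median would mostly reflect the censoring rule;
* the over-limit ratio (OLR) is the fraction of samples strictly above the
  food's maximum residue limit; foods without a legal limit have no OLR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MRLEntry, ResidueRecord, ValidationError

__all__ = ["FoodSummary", "substitute_censored", "detection_frequency",
           "conditional_median", "over_limit_ratio", "summarize",
           "summaries_to_frame", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.01  # mg kg^-1, the quantification limit


@dataclass(frozen=True)
class FoodSummary:
    """Per-group summary of a (possibly censored) record set."""

    group_key: Mapping[str, object]
    n: int
    df_ge_threshold: float
    median_all: float | None      # median of substituted values (or None in ND mode)
    median_above: float | None    # conditional median; None when nothing qualifies
    max_conc: float               # max of substituted values
    olr: float | None             # None when no MRL applies


def substitute_censored(record: ResidueRecord) -> float:
    """Concentration for numeric work: detects unchanged, non-detects ½·LOD."""
    if record.censored:
        return record.lod / 2.0
    return record.concentration


def detection_frequency(records: Sequence[ResidueRecord],
                        threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of samples whose *measured* concentration is >= threshold.

    Censored records never count as detections, whatever their LOD; a
    censored record whose LOD exceeds the threshold (impossible under the
    survey's LOD ranges, but possible in user data) is still a non-detect.
    """
    if len(records) == 0:
        raise ValidationError("detection frequency of an empty record set is undefined")
    hits = sum(1 for r in records
               if not r.censored and r.concentration >= threshold)
    return hits / len(records)


def conditional_median(records: Sequence[ResidueRecord],
                       threshold: float = DEFAULT_THRESHOLD) -> float | None:
    """Median (midpoint rule) of concentrations >= threshold; None when no
    sample qualifies."""
    vals = [r.concentration for r in records
            if not r.censored and r.concentration >= threshold]
    if not vals:
        return None
    return float(np.median(vals))


def over_limit_ratio(records: Sequence[ResidueRecord],
                     mrl: MRLEntry | float | None) -> float | None:
    """Fraction of samples with concentration strictly above the MRL.

    A sample exactly at the limit is compliant (the MRL is a maximum
    permitted level).  Returns None when no limit exists; censored records
    never exceed.
    """
    limit = mrl.mrl if isinstance(mrl, MRLEntry) else mrl
    if limit is None:
        return None
    if len(records) == 0:
        raise ValidationError("over-limit ratio of an empty record set is undefined")
    hits = sum(1 for r in records if not r.censored and r.concentration > limit)
    return hits / len(records)


_GROUP_FIELDS = ("food", "category", "province", "year", "source")


def _key_of(record: ResidueRecord, fields: Sequence[str]) -> tuple:
    out = []
    for f in fields:
        v = getattr(record, f)
        out.append(v.value if hasattr(v, "value") else v)
    return tuple(out)


def summarize(records: Sequence[ResidueRecord],
              group_by: Sequence[str],
              mrl_table: Iterable[MRLEntry] | None = None,
              threshold: float = DEFAULT_THRESHOLD,
              median_all_mode: str = "substituted") -> list[FoodSummary]:
    """One :class:`FoodSummary` per observed combination of ``group_by``
    fields, ordered lexicographically by key for reproducible output.

    Over-limit ratios use each record's own food limit, so they are defined
    for any grouping: within a group, the denominator is the subset of
    samples whose food has a limit (None when no record's food has one).

    ``median_all_mode``: "substituted" computes the all-sample median on
    ½·LOD-substituted values; "nd_when_censored" reports None whenever a
    majority of the group is censored (the median sample is then itself a
    non-detect).
    """
    for f in group_by:
        if f not in _GROUP_FIELDS:
            raise ValidationError(f"unknown grouping field: {f!r}")
    if median_all_mode not in ("substituted", "nd_when_censored"):
        raise ValidationError(f"unknown median_all_mode: {median_all_mode!r}")
    mrl_by_food = {e.food: e.mrl for e in mrl_table} if mrl_table else {}

    groups: dict[tuple, list[ResidueRecord]] = {}
    for r in records:
        groups.setdefault(_key_of(r, group_by), []).append(r)

    out: list[FoodSummary] = []
    for key in sorted(groups, key=lambda k: tuple(map(str, k))):
        recs = groups[key]
        subst = np.array([substitute_censored(r) for r in recs])
        if median_all_mode == "nd_when_censored" and \
                sum(r.censored for r in recs) * 2 >= len(recs):
            median_all = None
        else:
            median_all = float(np.median(subst))
        # per-record limits: OLR over the subset of foods that have one
        with_limit = [r for r in recs if mrl_by_food.get(r.food) is not None]
        if with_limit:
            over = sum(1 for r in with_limit
                       if not r.censored and r.concentration > mrl_by_food[r.food])
            olr = over / len(with_limit)
        else:
            olr = None
        out.append(FoodSummary(
            group_key=dict(zip(group_by, key)),
            n=len(recs),
            df_ge_threshold=detection_frequency(recs, threshold),
            median_all=median_all,
            median_above=conditional_median(recs, threshold),
            max_conc=float(subst.max()),
            olr=olr,
        ))
    return out


def summaries_to_frame(summaries: Sequence[FoodSummary]) -> pd.DataFrame:
    """Flatten summaries into a DataFrame (group-key fields first)."""
    rows = []
    for s in summaries:
        row = dict(s.group_key)
        row.update(n=s.n, df_ge_threshold=s.df_ge_threshold,
                   median_all=s.median_all, median_above=s.median_above,
                   max_conc=s.max_conc, olr=s.olr)
        rows.append(row)
    return pd.DataFrame(rows)
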