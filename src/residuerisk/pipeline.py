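"""End-to-end pipeline: simulate → summarize → trend → risk, with a run
manifest so reruns are auditable (identical inputs and seed give identical
output digests, timestamp aside)."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from . import io as sio
from . import risk as srisk
from . import summary as ssummary
from . import synthetic as ssynth
from . import trend as strend
from .io import Category, EXPOSURE_CATEGORIES

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in ``stage``."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_digest: str
    seed: int
    timestamp: str
    input_digests: Mapping[str, str]  # keyed by file name

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None,
                 command: str = "all") -> RunManifest:
    """Run the configured stages and write artifacts plus a manifest.

    Config (YAML) keys: ``seed``; optional ``survey`` (path — omitted means
    simulate from the packaged specs or ``specs``), ``mrl`` (path, default
    packaged table), ``consumption`` (path, default packaged profiles),
    ``usage`` (path, optional), ``threshold``, ``n_iter``, ``cv``.
    """
    config_path = Path(config_path)
    try:
        config = yaml.safe_load(config_path.read_text(encoding="utf-8")) or {}
    except OSError as exc:
        raise PipelineError("config", str(exc)) from exc
    seed = int(config.get("seed", 0))
    out = Path(out_dir) if out_dir else config_path.parent / "out"
    out.mkdir(parents=True, exist_ok=True)
    threshold = float(config.get("threshold", ssummary.DEFAULT_THRESHOLD))
    input_digests: dict[str, str] = {}

    # --- simulate (optional) ------------------------------------------------
    survey_path = config.get("survey")
    if survey_path is None:
        try:
            specs = (ssynth.read_specs(config["specs"]) if "specs" in config
                     else ssynth.default_specs())
            records = ssynth.generate_survey(specs, ssynth.GeneratorConfig(seed=seed))
            survey_path = out / "survey.csv"
            sio.write_survey(records, survey_path)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
    else:
        survey_path = Path(survey_path)

    # --- summarize ----------------------------------------------------------
    try:
        records = sio.read_survey(survey_path)
        input_digests[Path(survey_path).name] = _sha256(Path(survey_path))
        if "mrl" in config:
            mrl_table = sio.read_mrl_table(config["mrl"])
            input_digests[Path(config["mrl"]).name] = _sha256(Path(config["mrl"]))
        else:
            mrl_table = ssynth.default_mrl_table()
        summaries = ssummary.summarize(records, ["food"], mrl_table, threshold)
        ssummary.summaries_to_frame(summaries).to_csv(out / "summary.csv",
                                                      index=False)
        by_cat = ssummary.summarize(records, ["category"], mrl_table, threshold)
        ssummary.summaries_to_frame(by_cat).to_csv(out / "summary_by_category.csv",
                                                   index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("summarize", str(exc)) from exc

    # --- trend --------------------------------------------------------------
    try:
        usage = sio.read_usage(config["usage"]) if "usage" in config else None
        if "usage" in config:
            input_digests[Path(config["usage"]).name] = _sha256(Path(config["usage"]))
        strend.annual_series(records, usage, threshold).to_csv(out / "trend.csv")
    except Exception as exc:
        raise PipelineError("trend", str(exc)) from exc

    # --- risk ---------------------------------------------------------------
    try:
        if "consumption" in config:
            profiles = sio.read_consumption(config["consumption"])
            input_digests[Path(config["consumption"]).name] = \
                _sha256(Path(config["consumption"]))
        else:
            profiles = srisk.default_consumption_profiles()
        sim = srisk.SimulationConfig(seed=seed,
                                     n_iter=int(config.get("n_iter", 10_000)),
                                     cv=float(config.get("cv", 0.10)))
        by_cat_records = {c: [r for r in records if r.category == c]
                          for c in EXPOSURE_CATEGORIES}
        rows = []
        for profile in profiles:
            cr = srisk.chronic_risk(profile, by_cat_records, sim)
            frac = cr.exceedance([0.1, 1.0])
            rows.append({
                "population": profile.population.value, "risk_type": "chronic",
                "category": "combined", "median": cr.percentiles[50.0],
                "p97_5": cr.percentiles[97.5], "max": cr.percentiles[100.0],
                "frac_gt_0.1": frac[0.1], "frac_gt_1": frac[1.0],
                "ar_upper": "",
                **{f"contrib_{c.value}": cr.contributions[c]
                   for c in EXPOSURE_CATEGORIES}})
            for cat in EXPOSURE_CATEGORIES:
                ar = srisk.acute_risk(profile, by_cat_records[cat], cat, sim)
                frac = ar.exceedance([0.1, 1.0])
                rows.append({
                    "population": profile.population.value, "risk_type": "acute",
                    "category": cat.value, "median": ar.percentiles[50.0],
                    "p97_5": ar.percentiles[97.5], "max": ar.percentiles[100.0],
                    "frac_gt_0.1": frac[0.1], "frac_gt_1": frac[1.0],
                    "ar_upper": ar.ar_upper})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "risk.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("risk", str(exc)) from exc

    manifest = RunManifest(
        command=command,
        config_digest=_digest_text(config_path.read_text(encoding="utf-8")),
        seed=seed,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        input_digests=input_digests,
    )
    manifest.write(out / "manifest.json")
    return manifest
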