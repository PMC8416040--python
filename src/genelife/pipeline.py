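"""End-to-end pipeline: scoring -> models -> interaction -> indicators.

``run_pipeline`` executes the four analysis stages on a validated cohort
and returns a results bundle (per-subject scores, the separate-association
table, the 3x3 joint grid, the RERI panel, the indicator panel and a run
log). ``write_bundle`` serialises the bundle deterministically, so a fixed
(cohort, config, seed) always produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .epi import indicator_table
from .interaction import reri_panel
from .models import joint_effect_grid, separate_associations
from .scoring import score_cohort


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def run_pipeline(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Run the full analysis and return the results bundle.

    Bundle keys: ``scores`` (per-subject table), ``separate`` (Table-2-style
    long table), ``joint_grid`` (3x3 grid), ``reri`` (3-row panel),
    ``indicators`` (overall + per-GRS-group panel), ``log`` (config, seed,
    exclusion counts, GRS model metadata).
    """
    config = config or AnalysisConfig()
    stages: dict = {}
    log: dict = {"config": asdict(config)}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    scored, grs_model = _stage("scoring", score_cohort, cohort, config)
    log["n_subjects"] = int(len(cohort))
    log["n_grs_excluded"] = int(scored["grs"].isna().sum())
    log["grs_model"] = {
        "reference": grs_model.reference,
        "effects": grs_model.effects,
        "meta": grs_model.meta,
    }

    stages["scores"] = scored
    stages["separate"] = _stage("models", separate_associations, scored, config)
    stages["joint_grid"] = _stage("models", joint_effect_grid, scored, config)
    rng = np.random.default_rng(config.seed)
    stages["reri"] = _stage("interaction", reri_panel, scored, config, rng=rng)
    stages["indicators"] = _stage("epi_indicators", indicator_table, scored)
    stages["log"] = log
    return stages


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    """Write the bundle as delimited tables plus one structured summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("scores", "separate", "joint_grid", "reri", "indicators"):
        bundle[key].to_csv(outdir / f"{key}.csv", index=False, float_format="%.10g")
    summary = {
        "log": bundle["log"],
        "indicators": bundle["indicators"].to_dict(orient="records"),
        "reri": bundle["reri"].to_dict(orient="records"),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
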