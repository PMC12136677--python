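"""End-to-end pipeline driver: simulate → derive → train → summarize.

Produces a self-describing artifact directory: the cohort and derived tables,
per-response prediction tables, a metrics summary, the figure-analogue
summary CSVs and a JSON manifest with the seed, configuration hash and a
checksum of every output file.  Runs are idempotent for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .analysis import fit_group_trends, ordering_check, stratified_summary, trend_table
from .bioparams import derive_all
from .io import read_cohort, write_cohort, write_config
from .schema import SchemaError
from .regression import default_feature_spec, train_linear_svr
from .simulate import GeneratorConfig, calibrate_defaults, generate_cohort

log = logging.getLogger("biaindex")

__all__ = ["run_pipeline", "StageError"]

RESPONSES = ("I_r", "I_Xc", "theta")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    outdir,
    config: Optional[GeneratorConfig] = None,
    input_csv=None,
    seed: Optional[int] = None,
    responses: Sequence[str] = RESPONSES,
    split_seeds: int = 1,
) -> Path:
    """Execute the full analysis; returns the artifact directory.

    Either ``input_csv`` (an existing cohort CSV) or ``config`` (a generator
    configuration; defaults to the calibrated one) provides the cohort.
    ``seed`` overrides the config seed and seeds the train/holdout splits.
    With ``split_seeds > 1`` the metrics summary reports the per-response
    mean ± sd over that many seeded splits instead of a single split.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "stages": {}, "files": {}}
    t0 = time.time()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"started_s": round(time.time() - t0, 3)}
        return time.time()

    def done(name, start, **info):
        manifest["stages"][name].update(elapsed_s=round(time.time() - start, 3), **info)

    # --- obtain cohort ------------------------------------------------------
    t = stage("cohort")
    try:
        if input_csv is not None:
            cohort, rejections = read_cohort(input_csv)
            manifest["input_csv"] = str(input_csv)
            if seed is None:
                seed = 0
        else:
            config = config or calibrate_defaults()
            if seed is not None:
                config = config.model_copy(update={"seed": int(seed)})
            seed = config.seed
            result = generate_cohort(config)
            cohort = result.table
            rejections = pd.DataFrame(columns=["row", "subject_id", "reason"])
            write_config(config, outdir / "generator_config.toml")
            manifest["generator_warnings"] = result.warnings
    except SchemaError:
        raise  # validation failure, not a stage crash
    except Exception as exc:
        raise StageError("cohort", exc) from exc
    manifest["seed"] = int(seed)
    write_cohort(cohort, outdir / "cohort.csv")
    if len(rejections):
        rejections.to_csv(outdir / "rejections.csv", index=False)
    done("cohort", t, n_subjects=len(cohort), n_rejected=len(rejections))

    # --- derive -------------------------------------------------------------
    t = stage("derive")
    try:
        derived = derive_all(cohort)
    except Exception as exc:
        raise StageError("derive", exc) from exc
    derived.table.to_csv(outdir / "derived.csv", index=False)
    if len(derived.rejections):
        derived.rejections.to_csv(outdir / "derive_rejections.csv", index=False)
    done("derive", t, n_derived=len(derived.table), warnings=derived.warnings)

    # --- train --------------------------------------------------------------
    t = stage("train")
    metrics_rows = []
    try:
        for response in responses:
            spec = default_feature_spec(response)
            per_split = []
            for k in range(split_seeds):
                res = train_linear_svr(derived.table, spec, seed=int(seed) + k)
                per_split.append(res)
            res = per_split[0]
            res.predictions.to_csv(
                outdir / f"predictions_{response}.csv", index=False
            )
            for label, metrics in (
                ("train", [r.train_metrics for r in per_split]),
                ("holdout", [r.test_metrics for r in per_split]),
            ):
                frame = pd.DataFrame([m.as_dict() for m in metrics])
                row = {
                    "response": response,
                    "model": "linear_svr",
                    "evaluation": label,
                    "n_splits": split_seeds,
                }
                for col in ("RMSE", "R2", "MSE", "MAE"):
                    row[col] = frame[col].mean()
                    row[f"{col}_sd"] = frame[col].std(ddof=1) if split_seeds > 1 else 0.0
                metrics_rows.append(row)
    except Exception as exc:
        raise StageError("train", exc) from exc
    pd.DataFrame(metrics_rows).to_csv(outdir / "metrics_summary.csv", index=False)
    done("train", t, responses=list(responses))

    # --- summarize ----------------------------------------------------------
    t = stage("summarize")
    try:
        table = derived.table
        sex_med = stratified_summary(table, by="sex", statistic="median")
        sex_mean = stratified_summary(table, by="sex", statistic="mean")
        st_med = stratified_summary(table, by="weight_status", statistic="median")
        st_mean = stratified_summary(table, by="weight_status", statistic="mean")
        pd.concat([sex_med, sex_mean]).to_csv(outdir / "fig2_sex_summaries.csv", index=False)
        pd.concat([st_med, st_mean]).to_csv(outdir / "fig4_status_summaries.csv", index=False)
        lines, notices = fit_group_trends(table)
        trend_table(lines).to_csv(outdir / "fig3_trends.csv", index=False)
        orderings = ordering_check(pd.concat([st_med, st_mean]), pd.concat([sex_med, sex_mean]))
        (outdir / "ordering_report.json").write_text(
            json.dumps(orderings, indent=2, default=str)
        )
    except Exception as exc:
        raise StageError("summarize", exc) from exc
    done("summarize", t, trend_notices=notices)

    # --- manifest -----------------------------------------------------------
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    manifest["total_elapsed_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
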