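"""End-to-end pipeline orchestration, log validation and run manifests."""

from __future__ import annotations

import json
import os
import zlib

import pandas as pd

from . import descriptive, models, preprocess
from .config import ModelSpec, PipelineConfig, config_hash, config_to_dict
from .synthetic import simulate_cohort

__all__ = ["run_pipeline", "validate_logs", "stage_seed"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the top-level seed."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


_SCHEMAS = {
    "sound": {"columns": {"participant_id": "str", "timestamp": "datetime",
                          "spl": "float", "sml": "float", "snr": "float",
                          "soundscape": "category"},
              "ranges": {"spl": (-20, 140), "sml": (0, 120), "snr": (-60, 60)}},
    "hr": {"columns": {"participant_id": "str", "timestamp": "datetime",
                       "hr": "float"},
           "ranges": {"hr": (1e-9, 300)}},
    "gps": {"columns": {"participant_id": "str", "timestamp": "datetime",
                        "latitude": "float", "longitude": "float"},
            "ranges": {"latitude": (-90, 90), "longitude": (-180, 180)}},
}


def validate_logs(path: str, schema: str) -> dict:
    """Validate a CSV log file against one of the known schemas.

    Checks column presence, parseability, value ranges and per-participant
    timestamp monotonicity.  Returns a report dict with ``passed`` and
    row-level diagnostics; raises if the file cannot be read at all.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; one of {sorted(_SCHEMAS)}")
    spec = _SCHEMAS[schema]
    df = pd.read_csv(path)
    problems: list[dict] = []
    for col, kind in spec["columns"].items():
        if col not in df.columns:
            problems.append({"kind": "missing_column", "column": col})
    if problems:
        return {"passed": False, "n_rows": len(df), "problems": problems}
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    for i in df.index[ts.isna()][:20]:
        problems.append({"kind": "bad_timestamp", "row": int(i)})
    for col, (lo, hi) in spec["ranges"].items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        for i in df.index[bad][:20]:
            problems.append({"kind": "out_of_range", "column": col, "row": int(i),
                             "value": None if pd.isna(vals[i]) else float(vals[i])})
    warnings_list: list[dict] = []
    if not ts.isna().any():
        for pid, g in df.assign(__ts=ts).groupby("participant_id"):
            if not g["__ts"].is_monotonic_increasing:
                warnings_list.append({"kind": "non_monotonic_timestamps",
                                      "participant": str(pid)})
    return {"passed": not problems, "n_rows": len(df),
            "problems": problems, "warnings": warnings_list}


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | None = None) -> dict:
    """Execute simulate -> preprocess -> fit -> describe and write artifacts.

    Every stage's outputs are written under the configured output
    directory together with a manifest recording stage order, artifact
    paths, record counts, the config hash and the seed.  Any stage
    failure aborts with the stage name attached.
    """
    import copy

    cfg = copy.deepcopy(config) if config is not None else PipelineConfig()
    cfg.validate()
    out = outdir or cfg.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(cfg), "seed": cfg.seed, "stages": []}

    def record_stage(name: str, **info) -> None:
        manifest["stages"].append({"stage": name, **info})

    stage = "simulate"
    try:
        gen_cfg = cfg.generator
        gen_cfg.seed = stage_seed(cfg.seed, "simulate")
        cohort = simulate_cohort(gen_cfg)
        paths = cohort.write(os.path.join(out, "logs"))
        record_stage(stage, outputs=paths,
                     counts={"sound_logs": len(cohort.sound_logs),
                             "hr_logs": len(cohort.hr_logs),
                             "gps_logs": len(cohort.gps_logs)})

        stage = "preprocess"
        records, report = preprocess.build_records(
            cohort.hr_logs, cohort.sound_logs,
            cohort.gps_logs if len(cohort.gps_logs) else None, cfg.preprocess)
        rec_path = os.path.join(out, "records.csv")
        records.to_csv(rec_path, index=False)
        rep_path = os.path.join(out, "filtration_report.json")
        with open(rep_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        esf = preprocess.effective_sampling_frequency(records, cfg.preprocess)
        record_stage(stage, outputs={"records": rec_path, "report": rep_path},
                     counts={"records": len(records),
                             "participants": int(records["participant_id"].nunique())},
                     effective_sampling=esf["grand_mean"])

        stage = "fit"
        fit_results = {}
        for fixed in cfg.models:
            spec = ModelSpec(fixed=fixed)
            fit = models.fit_model(records, spec)
            null = models.fit_effect_null(fit)
            effect = models.partial_r2(fit, null)
            fit_results[fixed] = {"fit": fit.to_dict(),
                                  "effect_size": effect.to_dict()}
            with open(os.path.join(out, f"model_{fixed}.json"), "w") as fh:
                json.dump(fit_results[fixed], fh, indent=1)
            with open(os.path.join(out, f"model_{fixed}.txt"), "w") as fh:
                fh.write(fit.summary() + "\n")
        record_stage(stage, outputs={m: os.path.join(out, f"model_{m}.json")
                                     for m in cfg.models},
                     counts={"models": len(cfg.models)})

        stage = "describe"
        quart, occ = descriptive.hourly_summaries(cohort.sound_logs)
        quart.to_csv(os.path.join(out, "hourly_quartiles.csv"), index=False)
        occ.to_csv(os.path.join(out, "hourly_occupancy.csv"), index=False)
        cdfs = descriptive.class_cdfs(cohort.sound_logs,
                                      seed=stage_seed(cfg.seed, "describe"))
        cdfs.to_csv(os.path.join(out, "class_cdfs.csv"), index=False)
        record_stage(stage, outputs={"hourly_quartiles":
                                     os.path.join(out, "hourly_quartiles.csv")})
    except Exception as exc:  # noqa: BLE001 - stage tagging, then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["config"] = config_to_dict(cfg)
    man_path = os.path.join(out, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    manifest["path"] = man_path
    return manifest
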