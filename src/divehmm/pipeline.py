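"""End-to-end pipeline driver: simulate -> segment -> features -> fit -> report.

Each stage reads and writes delimited-text artifacts in the output
directory and appends to a manifest (inputs, seeds, per-file SHA-256
hashes) that makes a rerun exactly reproducible.  A stage failure halts the
chain with the failing stage named; artifacts already written are kept.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from . import srkw
from .analysis import allocation_summary, chisq_independence, duration_model, transition_report
from .features import SensorRecord, build_feature_table
from .hmm import canonical_relabel, em_fit
from .segmentation import detect_dives, downsample_depth, exclude_initial
from .selection import fit_model_grid
from .simulate import generate_deployment_signals, generate_dive_dataset

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log_stage(manifest: dict, stage: str, out_dir: Path, **counts) -> None:
    files = {
        p.name: _sha256(p) for p in sorted(out_dir.iterdir()) if p.is_file()
        and p.name != "manifest.json"
    }
    manifest["stages"].append({"stage": stage, "counts": counts,
                               "hashes": files})
    logger.info(json.dumps({"stage": stage, **counts}))


def run_pipeline(config: dict, out_dir, stages=("simulate", "fit", "report")):
    """Execute the requested stage chain into ``out_dir``.

    Recognized stages: ``simulate`` (dive-level feature table),
    ``simulate_signals`` + ``segment`` + ``features`` (signal-level path),
    ``fit`` (single 5-state sex-covariate model), ``select`` (full model
    grid), ``report`` (allocation, transition, duration and chi-square
    summaries).  Validation problems surface before any compute.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    fit_cfg = config.get("fit", {})
    manifest = {"config": config, "stages": [], "started": time.time()}
    needs_features = {"fit", "select", "report"} & set(stages)
    if needs_features and not (
        {"simulate", "features"} & set(stages)
        or (out_dir / "features.csv").exists()
        or config.get("features")
    ):
        raise PipelineError(
            "fit", ValueError("no feature table: add a simulate/features "
                              "stage or a 'features' config path")
        )

    features = None
    fit = None
    for stage in stages:
        try:
            if stage == "simulate":
                cfg = srkw.reference_config(seed=seed)
                table, _ = generate_dive_dataset(cfg, srkw.reference_emissions())
                features = table.drop(columns=["true_state"])
                dio.write_feature_table(features, out_dir / "features.csv")
                table.to_csv(out_dir / "truth.csv", index=False)
                _log_stage(manifest, stage, out_dir, n_dives=len(table))
            elif stage == "simulate_signals":
                cfg = srkw.reference_config(seed=seed)
                recs = generate_deployment_signals(cfg, srkw.reference_emissions())
                for rec in recs:
                    sensor = SensorRecord(
                        rec.deployment_id, rec.sample_rate, rec.time_s,
                        rec.depth_m, rec.acc, rec.heading_deg, rec.roll_deg,
                    )
                    dio.write_sensor_csv(sensor, out_dir / f"sensors_{rec.deployment_id}.csv")
                    dio.write_clicks_csv(rec.clicks, out_dir / f"clicks_{rec.deployment_id}.csv")
                    rec.truth.to_csv(out_dir / f"truth_{rec.deployment_id}.csv", index=False)
                _log_stage(manifest, stage, out_dir, n_deployments=len(recs))
            elif stage == "segment":
                rate = config["thresholds"]["analysis_rate_hz"]
                all_dives = []
                for path in sorted(out_dir.glob("sensors_*.csv")):
                    dep = path.stem.split("sensors_")[1]
                    sensor = dio.read_sensor_csv(path, deployment_id=dep)
                    series = downsample_depth(sensor.depth_series(), rate)
                    dives = exclude_initial(
                        detect_dives(series,
                                     config["thresholds"]["surface_m"],
                                     config["thresholds"]["min_max_depth_m"]),
                        config["thresholds"]["initial_exclusion_s"],
                    )
                    all_dives.extend(dives)
                dio.write_dive_table(all_dives, out_dir / "dives.csv")
                _log_stage(manifest, stage, out_dir, n_dives=len(all_dives))
            elif stage == "features":
                dives = dio.read_dive_table(out_dir / "dives.csv")
                meta = {d[0]: {"sex": d[1], "age_class": srkw._age_class(d[1], d[2]),
                               "year": d[3]} for d in srkw.DEPLOYMENTS}
                frames = []
                for dep in sorted({d.deployment_id for d in dives}):
                    sensor = dio.read_sensor_csv(
                        out_dir / f"sensors_{dep}.csv", deployment_id=dep)
                    clicks = dio.read_clicks_csv(out_dir / f"clicks_{dep}.csv")
                    frames.append(build_feature_table(
                        [d for d in dives if d.deployment_id == dep],
                        sensor, clicks, meta[dep],
                    ))
                features = pd.concat(frames, ignore_index=True)
                dio.write_feature_table(features, out_dir / "features.csv")
                _log_stage(manifest, stage, out_dir, n_rows=len(features))
            elif stage == "fit":
                features = _load_features(features, config, out_dir)
                fit = canonical_relabel(em_fit(
                    features,
                    n_states=int(fit_cfg.get("single_states", 5)),
                    transition_covariate=fit_cfg.get("single_covariate", "sex"),
                    n_restarts=int(fit_cfg.get("n_restarts", 200)),
                    max_iter=int(fit_cfg.get("max_iter", 2000)),
                    tol=float(fit_cfg.get("tol", 1e-6)),
                    seed=seed,
                ))
                dio.write_model_json(fit, out_dir / "model.json")
                _write_decoding(fit, out_dir)
                _log_stage(manifest, stage, out_dir, loglik=fit.loglik, aic=fit.aic)
            elif stage == "select":
                features = _load_features(features, config, out_dir)
                covs = [None if c == "null" else c
                        for c in fit_cfg.get("covariates", ["null", "sex", "age_class", "year"])]
                grid = fit_model_grid(
                    features,
                    states=tuple(fit_cfg.get("states", (3, 4, 5))),
                    covariates=tuple(covs),
                    n_restarts=int(fit_cfg.get("n_restarts", 200)),
                    max_iter=int(fit_cfg.get("max_iter", 2000)),
                    tol=float(fit_cfg.get("tol", 1e-6)),
                    seed=seed,
                )
                grid.table.to_csv(out_dir / "grid.csv", index=False)
                fit = canonical_relabel(grid.best_model)
                dio.write_model_json(fit, out_dir / "model.json")
                _write_decoding(fit, out_dir)
                _log_stage(manifest, stage, out_dir,
                           best_states=grid.best_key[0],
                           best_covariate=grid.best_key[1] or "null")
            elif stage == "report":
                features = _load_features(features, config, out_dir)
                if fit is None:
                    raise ValueError("report stage requires a fitted model "
                                     "(run fit or select first)")
                _report(fit, features, out_dir)
                _log_stage(manifest, stage, out_dir)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - named-stage halt contract
            (out_dir / "manifest.json").write_text(
                json.dumps(manifest, indent=1, sort_keys=True, default=str))
            raise PipelineError(stage, exc) from exc
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return out_dir


def _load_features(features, config, out_dir):
    if features is not None:
        return features
    path = config.get("features", out_dir / "features.csv")
    return dio.read_feature_table(path)


def _write_decoding(fit, out_dir: Path) -> None:
    fit.posterior.to_csv(out_dir / "posterior.csv", index=False)
    rows = [
        {"deployment_id": dep, "dive_index": i, "state": int(s)}
        for dep, path in sorted(fit.viterbi.items())
        for i, s in enumerate(path)
    ]
    pd.DataFrame(rows).to_csv(out_dir / "viterbi.csv", index=False)


def _report(fit, features, out_dir: Path) -> None:
    order = features.sort_values(["deployment_id", "start_s"])
    states = np.concatenate([fit.viterbi[d] for d in sorted(fit.viterbi)])
    alloc = allocation_summary(
        states, order["duration_s"].to_numpy(), order["sex"].to_numpy()
    )
    alloc.table.to_csv(out_dir / "allocation.csv", index=False)
    seconds = alloc.seconds_matrix().to_numpy()
    if seconds.shape[0] == 2 and (seconds > 0).all():
        chi = chisq_independence(seconds)
        diag = {"chi2": chi.statistic, "df": chi.df, "p": chi.p}
    else:
        diag = {"chi2": None}
    (out_dir / "diagnostics.json").write_text(
        json.dumps(diag, indent=1, sort_keys=True))
    if fit.spec.transition_covariate == "sex":
        mats = transition_report(fit)
        for sex_label, mat in mats.items():
            pd.DataFrame(mat).to_csv(
                out_dir / f"transitions_{sex_label}.csv", index=False)
        _write_dot(mats, out_dir / "transitions.dot")
    dm = duration_model(
        order["duration_s"].to_numpy(), states, order["sex"].to_numpy(),
        order["deployment_id"].to_numpy(),
    )
    dm.anova.to_csv(out_dir / "duration_anova.csv", index=False)
    dm.pairwise.to_csv(out_dir / "duration_tukey.csv", index=False)
    pd.DataFrame(
        [{"group": g, "letters": v} for g, v in sorted(dm.letters.items())]
    ).to_csv(out_dir / "duration_letters.csv", index=False)


def _write_dot(matrices: dict, path: Path) -> None:
    lines = ["digraph transitions {"]
    for sex_label, mat in matrices.items():
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                lines.append(
                    f'  "{sex_label}{i + 1}" -> "{sex_label}{j + 1}" '
                    f'[label="{mat[i, j]:.3f}"];'
                )
    lines.append("}")
    path.write_text("\n".join(lines))
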