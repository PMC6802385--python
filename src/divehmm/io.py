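"""Readers, writers and schema validation for the pipeline's file formats.

All tables are delimited text (CSV, header row, UTF-8).  The feature table
uses a fixed column order; every reader validates types and invariants and
raises a distinct, located error per violation class.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import SensorRecord
from .hmm import FitResult, HmmSpec
from .segmentation import DepthSeries, DiveSegment

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureTableError",
    "MissingColumnError",
    "NonFiniteFeatureError",
    "UnknownSexError",
    "InvariantError",
    "read_feature_table",
    "write_feature_table",
    "read_depth_csv",
    "write_depth_csv",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_clicks_csv",
    "write_clicks_csv",
    "write_dive_table",
    "read_dive_table",
    "write_model_json",
    "read_model_json",
    "load_config",
    "default_config",
]

FEATURE_COLUMNS = [
    "deployment_id", "dive_index", "start_s", "duration_s", "max_depth_m",
    "jerk_peak", "roll_med_deg", "heading_var", "buzz", "slow_click",
    "sex", "age_class", "year",
]
_NUMERIC_FEATURES = ["start_s", "duration_s", "max_depth_m", "jerk_peak",
                     "roll_med_deg", "heading_var"]


class FeatureTableError(ValueError):
    """Base class for feature-table validation failures."""


class MissingColumnError(FeatureTableError):
    pass


class NonFiniteFeatureError(FeatureTableError):
    pass


class UnknownSexError(FeatureTableError):
    pass


class InvariantError(FeatureTableError):
    pass


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise MissingColumnError(f"feature table missing column(s): {missing}")
    for col in _NUMERIC_FEATURES:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(float)))
        if bad.size:
            raise NonFiniteFeatureError(
                f"non-finite value in column {col!r} at row {bad[0]}"
            )
        table[col] = vals
    bad_sex = ~table["sex"].isin(["F", "M"])
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise UnknownSexError(
            f"unknown sex code {table['sex'].iloc[row]!r} at row {row}"
        )
    hv = table["heading_var"].to_numpy(float)
    out = (hv < 0) | (hv > 1)
    if out.any():
        row = int(np.flatnonzero(out)[0])
        raise InvariantError(
            f"heading_var out of [0, 1] at row {row} (column 'heading_var', "
            f"value {hv[row]})"
        )
    pos = table["max_depth_m"].to_numpy(float)
    if (pos < 0).any():
        row = int(np.flatnonzero(pos < 0)[0])
        raise InvariantError(f"negative max_depth_m at row {row}")
    table["buzz"] = table["buzz"].astype(int)
    table["slow_click"] = table["slow_click"].astype(int)
    table["year"] = table["year"].astype(int)
    return table


def read_feature_table(path) -> pd.DataFrame:
    """Load and validate a per-dive feature table.

    Rows are ordered by start time within deployment.  Raises a distinct
    error class for a missing column, a non-finite feature value, an
    unknown sex code, or an invariant violation, naming row and column.
    """
    table = validate_feature_table(pd.read_csv(path))
    return table.sort_values(["deployment_id", "start_s"]).reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    cols = FEATURE_COLUMNS + [c for c in table.columns if c not in FEATURE_COLUMNS]
    table[cols].to_csv(path, index=False)


def write_depth_csv(series: DepthSeries, path) -> None:
    pd.DataFrame({"time_s": series.time, "depth_m": series.depth}).to_csv(
        path, index=False
    )


def read_depth_csv(path, sample_rate: float | None = None,
                   deployment_id: str = "") -> DepthSeries:
    t = pd.read_csv(path)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t["time_s"])))
    return DepthSeries(t["time_s"].to_numpy(float),
                       t["depth_m"].to_numpy(float), sample_rate,
                       deployment_id)


def write_sensor_csv(record: SensorRecord, path) -> None:
    pd.DataFrame({
        "time_s": record.time,
        "depth_m": record.depth,
        "ax": record.acc[:, 0],
        "ay": record.acc[:, 1],
        "az": record.acc[:, 2],
        "heading_deg": record.heading_deg,
        "roll_deg": record.roll_deg,
    }).to_csv(path, index=False)


def read_sensor_csv(path, sample_rate: float | None = None,
                    deployment_id: str = "") -> SensorRecord:
    t = pd.read_csv(path)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t["time_s"])))
    return SensorRecord(
        deployment_id=deployment_id,
        sample_rate=sample_rate,
        time=t["time_s"].to_numpy(float),
        depth=t["depth_m"].to_numpy(float),
        acc=t[["ax", "ay", "az"]].to_numpy(float),
        heading_deg=t["heading_deg"].to_numpy(float),
        roll_deg=t["roll_deg"].to_numpy(float),
    )


def write_clicks_csv(clicks: pd.DataFrame, path) -> None:
    out = clicks.copy()
    if "event_type" not in out.columns:
        out["event_type"] = "click"
    if "assigned" not in out.columns:
        out["assigned"] = 1
    out[["time_s", "event_type", "assigned"]].to_csv(path, index=False)


def read_clicks_csv(path) -> pd.DataFrame:
    clicks = pd.read_csv(path)
    if "time_s" not in clicks.columns:
        raise MissingColumnError("click table missing column 'time_s'")
    if "assigned" not in clicks.columns:
        clicks["assigned"] = 1
    return clicks


def write_dive_table(dives: list[DiveSegment], path) -> None:
    pd.DataFrame([
        {
            "deployment_id": d.deployment_id,
            "dive_index": d.dive_index,
            "start_s": d.start_time,
            "end_s": d.end_time,
            "duration_s": d.duration,
            "max_depth_m": d.max_depth,
            "bottom_start_s": d.bottom_start,
            "bottom_end_s": d.bottom_end,
        }
        for d in dives
    ]).to_csv(path, index=False)


def read_dive_table(path) -> list[DiveSegment]:
    table = pd.read_csv(path)
    dives = []
    for _, r in table.iterrows():
        d = DiveSegment(
            deployment_id=str(r["deployment_id"]),
            dive_index=int(r["dive_index"]),
            start_time=float(r["start_s"]),
            end_time=float(r["end_s"]),
            max_depth=float(r["max_depth_m"]),
            bottom_start=float(r["bottom_start_s"]),
            bottom_end=float(r["bottom_end_s"]),
        )
        dives.append(d)
    return dives


def write_model_json(fit: FitResult, path, seed: int | None = None) -> None:
    spec = fit.spec
    payload = {
        "seed": seed,
        "n_states": spec.n_states,
        "cont_coef": spec.cont_coef.tolist(),
        "cont_sd": spec.cont_sd.tolist(),
        "bin_coef": spec.bin_coef.tolist(),
        "trans_coef": spec.trans_coef.tolist(),
        "pi": spec.pi.tolist(),
        "transition_covariate": spec.transition_covariate,
        "covariate_levels": list(spec.covariate_levels),
        "loglik": fit.loglik,
        "k": fit.k,
        "aic": fit.aic,
        "n_restarts_converged": fit.n_restarts_converged,
        "state_stats": {k: v.tolist() for k, v in fit.state_stats.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_model_json(path) -> tuple[HmmSpec, dict]:
    payload = json.loads(Path(path).read_text())
    spec = HmmSpec(
        n_states=payload["n_states"],
        cont_coef=np.array(payload["cont_coef"]),
        cont_sd=np.array(payload["cont_sd"]),
        bin_coef=np.array(payload["bin_coef"]),
        trans_coef=np.array(payload["trans_coef"]),
        pi=np.array(payload["pi"]),
        transition_covariate=payload["transition_covariate"],
        covariate_levels=payload["covariate_levels"],
    )
    return spec, payload


# ---------------------------------------------------------------------------
# Configuration

CONFIG_VERSION = 1

_DEFAULT_CONFIG = {
    "version": CONFIG_VERSION,
    "thresholds": {
        "surface_m": 0.5,
        "min_max_depth_m": 1.0,
        "bottom_fraction": 0.70,
        "buzz_ici_s": 0.010,
        "slow_ici_s": 0.100,
        "bout_gap_s": 2.0,
        "initial_exclusion_s": 300.0,
        "analysis_rate_hz": 5.0,
    },
    "fit": {
        "states": [3, 4, 5],
        "covariates": ["null", "sex", "age_class", "year"],
        "n_restarts": 200,
        "max_iter": 2000,
        "tol": 1.0e-6,
    },
    "seed": 0,
}


def default_config() -> dict:
    return json.loads(json.dumps(_DEFAULT_CONFIG))


def load_config(path) -> dict:
    """Load a YAML config, overlaying the versioned default schema."""
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    if user.get("version", CONFIG_VERSION) != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {user.get('version')}")
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg
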