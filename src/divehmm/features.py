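"""Per-dive response variables from kinematic streams and click events.

Six variables per dive: maximum depth (m); jerk peak (norm of the
first-differenced triaxial acceleration times the sample rate, maximized
over the bottom phase); roll (median absolute roll, degrees); heading
variance (circular variance of heading, in [0, 1]); buzz presence (any
inter-click interval <= 10 ms within a click bout); slow-click presence
(any inter-click interval > 100 ms within a bout).  All but jerk peak are
computed over the whole dive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import DepthSeries, DiveSegment

__all__ = [
    "SensorRecord",
    "jerk_peak",
    "circular_variance",
    "roll_median",
    "classify_click_train",
    "build_feature_table",
]

logger = logging.getLogger(__name__)

JERK_EPSILON = 1e-6
BUZZ_ICI_S = 0.010
SLOW_ICI_S = 0.100
BOUT_GAP_S = 2.0


@dataclass
class SensorRecord:
    """Time-aligned full-rate kinematic streams for one deployment."""

    deployment_id: str
    sample_rate: float
    time: np.ndarray
    depth: np.ndarray
    acc: np.ndarray  # (T, 3)
    heading_deg: np.ndarray
    roll_deg: np.ndarray

    def depth_series(self) -> DepthSeries:
        return DepthSeries(self.time, self.depth, self.sample_rate,
                           self.deployment_id)


def jerk_peak(
    acc: np.ndarray,
    sample_rate: float,
    epsilon: float = JERK_EPSILON,
) -> float:
    """Maximum jerk magnitude: fs * ||a(t+dt) - a(t)||_2 over the window.

    The caller passes acceleration already sliced to the bottom phase.
    Floored at a small epsilon so the natural log stays defined.
    """
    acc = np.asarray(acc, float)
    if acc.shape[0] < 2:
        warnings.warn("bottom phase shorter than 2 samples; jerk peak set to "
                      "epsilon", stacklevel=2)
        return epsilon
    jerk = sample_rate * np.linalg.norm(np.diff(acc, axis=0), axis=1)
    return float(max(jerk.max(), epsilon))


def circular_variance(headings_deg: np.ndarray) -> float:
    """1 minus the mean resultant length of the heading unit vectors."""
    h = np.radians(np.asarray(headings_deg, float))
    if h.size == 0:
        raise ValueError("circular_variance requires at least one heading")
    r = np.hypot(np.cos(h).mean(), np.sin(h).mean())
    return float(1.0 - r)


def roll_median(roll_deg: np.ndarray) -> float:
    """Median absolute roll in degrees."""
    r = np.asarray(roll_deg, float)
    if r.size == 0:
        raise ValueError("roll_median requires at least one sample")
    return float(np.median(np.abs(r)))


def classify_click_train(
    times_s: np.ndarray,
    buzz_ici_s: float = BUZZ_ICI_S,
    slow_ici_s: float = SLOW_ICI_S,
    bout_gap_s: float = BOUT_GAP_S,
) -> tuple[bool, bool]:
    """Flag buzz and slow-click presence from a dive's click times.

    Clicks are partitioned into bouts at gaps exceeding ``bout_gap_s``;
    within each bout consecutive inter-click intervals at or below
    ``buzz_ici_s`` flag a buzz and intervals above ``slow_ici_s`` flag slow
    clicking.  Intervals between the two thresholds (regular fast clicking)
    set neither flag.
    """
    t = np.sort(np.asarray(times_s, float))
    if t.size < 2:
        return False, False
    ici = np.diff(t)
    within = ici <= bout_gap_s
    buzz = bool(np.any(within & (ici <= buzz_ici_s)))
    slow = bool(np.any(within & (ici > slow_ici_s)))
    return buzz, slow


def build_feature_table(
    dives: list[DiveSegment],
    record: SensorRecord,
    clicks: pd.DataFrame,
    covariates: dict,
    epsilon: float = JERK_EPSILON,
) -> pd.DataFrame:
    """Assemble the per-dive feature table for one deployment.

    ``clicks`` needs columns time_s and (optionally) assigned; only events
    assigned to the tagged whale count.  ``covariates`` supplies sex,
    age_class and year.  Dives without sensor coverage are dropped and
    logged.  Continuous features are floored at epsilon so their natural
    logs are finite.
    """
    t = record.time
    if "assigned" in clicks.columns:
        clicks = clicks[clicks["assigned"].astype(bool)]
    ct = clicks["time_s"].to_numpy(float)
    rows = []
    for dive in dives:
        mask = (t >= dive.start_time) & (t <= dive.end_time)
        if not mask.any() or dive.end_time > t[-1] + 1e-9:
            logger.warning("%s dive %d lacks sensor coverage; dropped",
                           dive.deployment_id, dive.dive_index)
            continue
        bmask = (t >= dive.bottom_start) & (t <= dive.bottom_end)
        buzz, slow = classify_click_train(
            ct[(ct >= dive.start_time) & (ct <= dive.end_time)]
        )
        rows.append(
            {
                "deployment_id": dive.deployment_id,
                "dive_index": dive.dive_index,
                "start_s": dive.start_time,
                "duration_s": dive.duration,
                "max_depth_m": max(dive.max_depth, epsilon),
                "jerk_peak": jerk_peak(record.acc[bmask], record.sample_rate,
                                       epsilon),
                "roll_med_deg": max(roll_median(record.roll_deg[mask]), epsilon),
                "heading_var": max(circular_variance(record.heading_deg[mask]),
                                   epsilon),
                "buzz": int(buzz),
                "slow_click": int(slow),
                "sex": covariates["sex"],
                "age_class": covariates.get("age_class", "adult"),
                "year": covariates.get("year", 0),
            }
        )
    return pd.DataFrame(rows)
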