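"""Synthetic dive datasets with known behavioral-state structure.

Two levels of emulation:

* :func:`generate_dive_dataset` draws per-dive feature vectors directly from
  a state x sex emission specification along a first-order Markov chain of
  latent states — the statistical structure the covariate HMM assumes —
  and returns the true state labels alongside.
* :func:`generate_deployment_signals` additionally renders each deployment
  as 50 Hz sensor streams (depth, triaxial acceleration, heading, roll) and
  an echolocation click-event table, so that dive segmentation and feature
  extraction can be exercised end to end against known truth.

Continuous per-dive variables are log-normal, parameterized by matching the
median and quartiles of a :class:`LogNormalSpec`; binary variables are
Bernoulli.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LogNormalSpec",
    "StateEmissionSpec",
    "GeneratorConfig",
    "derive_lognormal_params",
    "generate_dive_dataset",
    "generate_deployment_signals",
]

_Z_UPPER_QUARTILE = norm.ppf(0.75)  # 0.67449...

CONTINUOUS_CHANNELS = ("max_depth", "jerk_peak", "roll", "heading_variance")
BINARY_CHANNELS = ("buzz", "slow_click")

# heading variance lives in [0, 1]; log-normal draws above 1 are clipped
# just below it, which leaves the target quartiles untouched whenever the
# third quartile itself is below 1.
_HEADING_VAR_CEIL = 1.0 - 1e-6


@dataclass(frozen=True)
class LogNormalSpec:
    """A positive, right-skewed variable summarized by its quartiles."""

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if min(self.median, self.q1, self.q3) <= 0:
            raise ValueError(f"quartile summary must be positive: {self}")
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError(f"requires q1 <= median <= q3: {self}")


@dataclass(frozen=True)
class StateEmissionSpec:
    """Emission distributions of one behavioral state, keyed by sex (F/M)."""

    max_depth: dict[str, LogNormalSpec]
    jerk_peak: dict[str, LogNormalSpec]
    roll: dict[str, LogNormalSpec]
    heading_variance: dict[str, LogNormalSpec]
    buzz_prob: dict[str, float]
    slow_click_prob: dict[str, float]
    duration: dict[str, LogNormalSpec]

    def __post_init__(self) -> None:
        for probs in (self.buzz_prob, self.slow_click_prob):
            for sex, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of [0,1] for {sex}: {p}")

    def lognormal(self, channel: str, sex: str) -> LogNormalSpec:
        return getattr(self, channel)[sex]


@dataclass
class GeneratorConfig:
    """Study design: deployments, covariates, latent-chain parameters."""

    n_states: int
    deployments: list[str]
    sex: dict[str, str]
    transition_matrix: dict[str, np.ndarray]
    initial_distribution: np.ndarray
    seed: int = 0
    dives_per_deployment: tuple[int, int] = (180, 400)
    age_class: dict[str, str] = field(default_factory=dict)
    year: dict[str, int] = field(default_factory=dict)
    descent_speed_m_s: float = 2.0
    surface_mean_s: float = 20.0
    surface_min_s: float = 2.0

    def __post_init__(self) -> None:
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        if abs(self.initial_distribution.sum() - 1.0) > 1e-12:
            raise ValueError("initial distribution must sum to 1")
        for sex, mat in self.transition_matrix.items():
            mat = np.asarray(mat, float)
            self.transition_matrix[sex] = mat
            if mat.shape != (self.n_states, self.n_states):
                raise ValueError(f"transition matrix for {sex} has shape {mat.shape}")
            if np.abs(mat.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"transition rows for {sex} must sum to 1")
        if len(self.initial_distribution) != self.n_states:
            raise ValueError("initial distribution length != n_states")
        missing = [d for d in self.deployments if d not in self.sex]
        if missing:
            raise ValueError(f"deployments without a sex label: {missing}")


def derive_lognormal_params(spec: LogNormalSpec) -> tuple[float, float]:
    """Map a (median, q1, q3) summary to log-normal (mu, sigma).

    mu = ln(median) and sigma = ln(q3/q1) / (2 z) with z the standard-normal
    upper quartile, so that the log-normal's theoretical quartiles reproduce
    the summary (exactly when the summary is quartile-symmetric on the log
    scale, i.e. median = sqrt(q1 q3)).
    """
    mu = float(np.log(spec.median))
    sigma = float(np.log(spec.q3 / spec.q1) / (2.0 * _Z_UPPER_QUARTILE))
    if spec.q1 == spec.q3:
        warnings.warn(
            f"degenerate quartile summary {spec}: sigma = 0 (point mass)",
            stacklevel=2,
        )
    return mu, sigma


def _simulate_chain(
    rng: np.random.Generator, n: int, pi: np.ndarray, P: np.ndarray
) -> np.ndarray:
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(len(pi), p=pi)
    for t in range(1, n):
        states[t] = rng.choice(P.shape[1], p=P[states[t - 1]])
    return states


def _draw_lognormal(
    rng: np.random.Generator, spec: LogNormalSpec, size: int
) -> np.ndarray:
    mu, sigma = derive_lognormal_params(spec)
    return np.exp(mu + sigma * rng.standard_normal(size))


def _check_emissions(config: GeneratorConfig, emissions) -> None:
    if len(emissions) != config.n_states:
        raise ValueError(
            f"{len(emissions)} emission specs for n_states={config.n_states}"
        )


def generate_dive_dataset(
    config: GeneratorConfig,
    emissions: list[StateEmissionSpec],
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Draw a dive-level feature table with latent-state truth labels.

    Returns the feature table (one row per dive, the canonical feature
    columns plus ``true_state`` with 1-based labels) and a mapping of
    deployment id to its true state sequence.
    """
    _check_emissions(config, emissions)
    rng = np.random.default_rng(config.seed)
    rows: list[pd.DataFrame] = []
    truth: dict[str, np.ndarray] = {}
    for dep in config.deployments:
        sex = config.sex[dep]
        n = int(rng.integers(config.dives_per_deployment[0],
                             config.dives_per_deployment[1] + 1))
        states = _simulate_chain(
            rng, n, config.initial_distribution, config.transition_matrix[sex]
        )
        truth[dep] = states + 1
        cont = {ch: np.empty(n) for ch in CONTINUOUS_CHANNELS}
        dur = np.empty(n)
        binry = {ch: np.zeros(n, dtype=int) for ch in BINARY_CHANNELS}
        for j in range(config.n_states):
            idx = np.flatnonzero(states == j)
            if idx.size == 0:
                continue
            spec = emissions[j]
            for ch in CONTINUOUS_CHANNELS:
                cont[ch][idx] = _draw_lognormal(rng, spec.lognormal(ch, sex), idx.size)
            dur[idx] = _draw_lognormal(rng, spec.duration[sex], idx.size)
            binry["buzz"][idx] = rng.random(idx.size) < spec.buzz_prob[sex]
            binry["slow_click"][idx] = rng.random(idx.size) < spec.slow_click_prob[sex]
        cont["heading_variance"] = np.minimum(
            cont["heading_variance"], _HEADING_VAR_CEIL
        )
        gaps = np.maximum(
            rng.exponential(config.surface_mean_s, n), config.surface_min_s
        )
        start = np.concatenate([[gaps[0]], gaps[1:]]).cumsum() + np.concatenate(
            [[0.0], dur[:-1]]
        ).cumsum()
        rows.append(
            pd.DataFrame(
                {
                    "deployment_id": dep,
                    "dive_index": np.arange(n),
                    "start_s": start,
                    "duration_s": dur,
                    "max_depth_m": cont["max_depth"],
                    "jerk_peak": cont["jerk_peak"],
                    "roll_med_deg": cont["roll"],
                    "heading_var": cont["heading_variance"],
                    "buzz": binry["buzz"],
                    "slow_click": binry["slow_click"],
                    "sex": sex,
                    "age_class": config.age_class.get(dep, "adult"),
                    "year": config.year.get(dep, 0),
                    "true_state": states + 1,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return table, truth


# ---------------------------------------------------------------------------
# Signal-level emulation


@dataclass
class SyntheticDeployment:
    """50 Hz sensor streams plus click events and the truth dive table."""

    deployment_id: str
    sample_rate: float
    time_s: np.ndarray
    depth_m: np.ndarray
    acc: np.ndarray  # (T, 3) in g
    heading_deg: np.ndarray
    roll_deg: np.ndarray
    clicks: pd.DataFrame  # time_s, assigned
    truth: pd.DataFrame  # per-dive targets and true state


def generate_deployment_signals(
    config: GeneratorConfig,
    emissions: list[StateEmissionSpec],
    sample_rate: float = 50.0,
) -> list[SyntheticDeployment]:
    """Render each deployment as raw sensor streams with truth dives.

    Dives are trapezoids: descent and ascent at ``config.descent_speed_m_s``
    with the drawn maximum depth held (with slight wobble) for the remaining
    duration; surface intervals are exponential with a floor.  A jerk
    transient of the dive's target amplitude is injected in the bottom
    phase; heading is wrapped-Gaussian with dispersion matched to the target
    circular variance; click trains follow the dive's buzz/slow-click flags.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    _check_emissions(config, emissions)
    rng = np.random.default_rng(config.seed)
    fs = float(sample_rate)
    dt = 1.0 / fs
    out: list[SyntheticDeployment] = []
    for dep in config.deployments:
        sex = config.sex[dep]
        n = int(rng.integers(config.dives_per_deployment[0],
                             config.dives_per_deployment[1] + 1))
        states = _simulate_chain(
            rng, n, config.initial_distribution, config.transition_matrix[sex]
        )
        depth_parts: list[np.ndarray] = []
        truth_rows = []
        click_times: list[np.ndarray] = []
        jerk_marks = []  # (sample index, amplitude)
        dive_bounds = []  # sample index ranges per dive
        t_cursor = 0.0
        n_samples = 0

        def _extend_surface(duration: float) -> None:
            nonlocal t_cursor, n_samples
            k = max(int(round(duration * fs)), 1)
            depth_parts.append(np.zeros(k))
            n_samples += k
            t_cursor += k * dt

        for i in range(n):
            _extend_surface(
                max(rng.exponential(config.surface_mean_s), config.surface_min_s)
            )
            spec = emissions[states[i]]
            depth = max(float(_draw_lognormal(rng, spec.lognormal("max_depth", sex), 1)[0]), 1.05)
            travel = 2.0 * depth / config.descent_speed_m_s
            dur = max(float(_draw_lognormal(rng, spec.duration[sex], 1)[0]), travel + 1.0)
            jerk = float(_draw_lognormal(rng, spec.lognormal("jerk_peak", sex), 1)[0])
            roll = float(_draw_lognormal(rng, spec.lognormal("roll", sex), 1)[0])
            hvar = min(
                float(_draw_lognormal(rng, spec.lognormal("heading_variance", sex), 1)[0]),
                _HEADING_VAR_CEIL,
            )
            buzz = bool(rng.random() < spec.buzz_prob[sex])
            slow = bool(rng.random() < spec.slow_click_prob[sex])

            k = max(int(round(dur * fs)), 4)
            tt = np.arange(k) * dt
            half = travel / 2.0
            prof = np.minimum(
                config.descent_speed_m_s * tt,
                config.descent_speed_m_s * (k * dt - tt),
            )
            prof = np.minimum(prof, depth)
            # slight bottom wobble, kept well inside the bottom-phase band
            bottom = prof >= depth - 1e-9
            prof = prof + bottom * (0.01 * depth * np.sin(tt * 1.3))
            prof = np.clip(prof, 0.0, None)
            prof[0] = min(prof[0], 0.4)  # start below the surface threshold
            prof[-1] = min(prof[-1], 0.4)
            start_t = t_cursor
            i0 = n_samples
            depth_parts.append(prof)
            n_samples += k
            t_cursor += k * dt
            end_t = t_cursor
            dive_bounds.append((i0, i0 + k))

            bot_idx = i0 + np.flatnonzero(prof >= 0.70 * depth)
            mark = int(rng.integers(bot_idx[0], bot_idx[-1] + 1)) if bot_idx.size else i0
            jerk_marks.append((mark, jerk))

            # click trains: slow regime early, buzz burst late, >3 s apart
            if slow:
                t0 = start_t + 0.1 * dur
                icis = rng.uniform(0.15, 0.4, size=8)
                train = t0 + np.concatenate([[0.0], np.cumsum(icis)])
                click_times.append(train[train < end_t - 0.5])
            if buzz:
                t0 = start_t + 0.65 * dur
                train = t0 + 0.005 * np.arange(60)
                click_times.append(train[train < end_t - 0.2])

            truth_rows.append(
                {
                    "deployment_id": dep,
                    "dive_index": i,
                    "state": states[i] + 1,
                    "start_s": start_t,
                    "end_s": end_t,
                    "duration_s": dur,
                    "max_depth_m": depth,
                    "jerk_peak": jerk,
                    "roll_med_deg": roll,
                    "heading_var": hvar,
                    "buzz": int(buzz),
                    "slow_click": int(slow),
                }
            )
        _extend_surface(max(rng.exponential(config.surface_mean_s),
                            config.surface_min_s))

        depth_m = np.concatenate(depth_parts)
        time_s = np.arange(n_samples) * dt
        acc = np.stack(
            [
                rng.normal(0.0, 0.004, n_samples),
                rng.normal(0.0, 0.004, n_samples),
                1.0 + rng.normal(0.0, 0.004, n_samples),
            ],
            axis=1,
        )
        for mark, amp in jerk_marks:
            acc[mark : mark + 3, 0] += amp / fs

        heading = rng.uniform(0.0, 360.0) * np.ones(n_samples)
        roll_deg = np.zeros(n_samples)
        for (i0, i1), row in zip(dive_bounds, truth_rows):
            v = row["heading_var"]
            sd = np.sqrt(max(-2.0 * np.log1p(-v), 0.0))
            base = rng.uniform(0.0, 2 * np.pi)
            heading[i0:i1] = np.degrees(
                np.mod(base + sd * rng.standard_normal(i1 - i0), 2 * np.pi)
            )
            signs = rng.choice([-1.0, 1.0], size=i1 - i0)
            roll_deg[i0:i1] = signs * row["roll_med_deg"] * (
                1.0 + rng.normal(0.0, 0.03, i1 - i0)
            )

        times = (
            np.sort(np.concatenate(click_times)) if click_times else np.empty(0)
        )
        clicks = pd.DataFrame({"time_s": times, "assigned": 1})
        out.append(
            SyntheticDeployment(
                deployment_id=dep,
                sample_rate=fs,
                time_s=time_s,
                depth_m=depth_m,
                acc=acc,
                heading_deg=heading,
                roll_deg=roll_deg,
                clicks=clicks,
                truth=pd.DataFrame(truth_rows),
            )
        )
    return out
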