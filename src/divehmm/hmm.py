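"""Covariate hidden Markov model for per-dive behavioral states.

The model: a first-order Markov chain over N latent states per deployment
(deployments are independent time series sharing one parameter set).  Each
dive emits six conditionally independent channels — four continuous
variables modeled as Gaussian on the natural-log scale with a sex effect on
the mean, and two binary variables modeled as Bernoulli with a logit-linear
sex effect.  Transition probabilities follow a baseline-category
multinomial logit per origin row, optionally with one deployment-level
covariate (sex, age class, or year); the baseline destination is state 1.

Fitting is by EM with multiple random restarts: the E-step is the scaled
forward-backward recursion; every M-step has a closed form because the
response covariate is a single binary indicator and transition covariates
have at most three levels, making the weighted logistic / multinomial-logit
regressions saturated (group-proportion MLEs).  The best restart by AIC is
retained.  Decoding is by Viterbi in log space with ties broken toward the
lower state index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HmmSpec",
    "FitResult",
    "transition_matrix",
    "emission_logdensity",
    "forward_loglik",
    "em_fit",
    "viterbi",
    "count_parameters",
    "aic",
    "canonical_relabel",
]

logger = logging.getLogger(__name__)

CONT_COLUMNS = ("max_depth_m", "jerk_peak", "roll_med_deg", "heading_var")
BIN_COLUMNS = ("buzz", "slow_click")
TRANSITION_COVARIATES = (None, "sex", "age_class", "year")

_PROB_FLOOR = 1e-10
_BERNOULLI_CLAMP = 1e-6
_SIGMA_FLOOR = 1e-4
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class HmmSpec:
    """Full parameterization of an N-state covariate HMM.

    ``cont_coef[j, v]`` holds (intercept, sex coefficient) for the mean of
    ln(channel v) in state j; ``cont_sd[j, v]`` its standard deviation.
    ``bin_coef[j, b]`` holds (logit intercept, sex coefficient).
    ``trans_coef[i, k-1]`` holds the multinomial-logit coefficients
    (intercept followed by one entry per transition-covariate column) for
    origin i and destination k >= 2; destination 1 is the baseline with
    logits fixed at zero.
    """

    n_states: int
    cont_coef: np.ndarray  # (N, 4, 2)
    cont_sd: np.ndarray  # (N, 4)
    bin_coef: np.ndarray  # (N, 2, 2)
    trans_coef: np.ndarray  # (N, N-1, 1+p)
    pi: np.ndarray  # (N,)
    transition_covariate: str | None = None
    covariate_levels: list = field(default_factory=list)  # year levels, sorted

    def __post_init__(self) -> None:
        self.cont_coef = np.asarray(self.cont_coef, float)
        self.cont_sd = np.asarray(self.cont_sd, float)
        self.bin_coef = np.asarray(self.bin_coef, float)
        self.trans_coef = np.asarray(self.trans_coef, float)
        self.pi = np.asarray(self.pi, float)
        if np.any(self.cont_sd <= 0):
            raise ValueError("continuous-channel standard deviations must be > 0")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_covariate_columns(self) -> int:
        return self.trans_coef.shape[2] - 1 if self.n_states > 1 else 0


def transition_matrix(spec: HmmSpec, covariate_values=()) -> np.ndarray:
    """Row-stochastic N x N matrix at the given covariate column values."""
    N = spec.n_states
    if N == 1:
        return np.ones((1, 1))
    z = np.concatenate([[1.0], np.asarray(covariate_values, float)])
    eta = np.zeros((N, N))
    eta[:, 1:] = spec.trans_coef @ z
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    return P / P.sum(axis=1, keepdims=True)


def _encode_sex(values) -> np.ndarray:
    arr = np.asarray(values)
    out = np.where(arr == "F", 0.0, np.where(arr == "M", 1.0, np.nan))
    if np.any(np.isnan(out.astype(float))):
        bad = sorted(set(arr[np.isnan(out.astype(float))]))
        raise ValueError(f"unknown sex code(s): {bad}")
    return out.astype(float)


def _transition_design(data: pd.DataFrame, covariate: str | None):
    """Per-deployment covariate column values and the level metadata."""
    if covariate not in TRANSITION_COVARIATES:
        raise ValueError(f"unknown transition covariate {covariate!r}")
    dep_meta = data.groupby("deployment_id", sort=True).first()
    if covariate is None:
        return {d: np.empty(0) for d in dep_meta.index}, []
    if covariate == "sex":
        vals = _encode_sex(dep_meta["sex"].to_numpy())
        return {d: np.array([v]) for d, v in zip(dep_meta.index, vals)}, []
    if covariate == "age_class":
        vals = (dep_meta["age_class"].to_numpy() == "adult").astype(float)
        return {d: np.array([v]) for d, v in zip(dep_meta.index, vals)}, []
    levels = sorted(dep_meta["year"].unique())
    z = {
        d: np.array([1.0 if y == lv else 0.0 for lv in levels[1:]])
        for d, y in zip(dep_meta.index, dep_meta["year"])
    }
    return z, levels


@dataclass
class _Deployment:
    deployment_id: str
    dive_index: np.ndarray
    Y: np.ndarray  # (T, 4) natural-log continuous features
    B: np.ndarray  # (T, 2) binary features
    sex: float
    z: np.ndarray  # transition covariate columns


def _prepare(data: pd.DataFrame, covariate: str | None):
    z_by_dep, levels = _transition_design(data, covariate)
    deployments = []
    for dep, grp in data.groupby("deployment_id", sort=True):
        grp = grp.sort_values("start_s" if "start_s" in grp else "dive_index")
        if len(grp) == 0:
            logger.warning("deployment %s empty; skipped", dep)
            continue
        Y = np.log(grp[list(CONT_COLUMNS)].to_numpy(float))
        if not np.all(np.isfinite(Y)):
            raise ValueError(f"non-finite ln features in deployment {dep}")
        deployments.append(
            _Deployment(
                deployment_id=dep,
                dive_index=grp["dive_index"].to_numpy(),
                Y=Y,
                B=grp[list(BIN_COLUMNS)].to_numpy(float),
                sex=float(_encode_sex([grp["sex"].iloc[0]])[0]),
                z=z_by_dep[dep],
            )
        )
    return deployments, levels


def _emission_loglik(spec: HmmSpec, dep: _Deployment) -> np.ndarray:
    """(T, N) log density of each dive under each state."""
    mean = spec.cont_coef[:, :, 0] + spec.cont_coef[:, :, 1] * dep.sex  # (N,4)
    sd = spec.cont_sd
    resid = dep.Y[:, None, :] - mean[None, :, :]
    ll = -0.5 * np.sum(
        (resid / sd[None]) ** 2 + 2.0 * np.log(sd[None]) + _LOG_2PI, axis=2
    )
    logit = spec.bin_coef[:, :, 0] + spec.bin_coef[:, :, 1] * dep.sex  # (N,2)
    p = 1.0 / (1.0 + np.exp(-logit))
    p = np.clip(p, _BERNOULLI_CLAMP, 1.0 - _BERNOULLI_CLAMP)
    ll += dep.B @ np.log(p).T + (1.0 - dep.B) @ np.log1p(-p).T
    return ll


def emission_logdensity(spec: HmmSpec, dive: pd.Series, state: int) -> float:
    """Log density of one dive's six channels under one state (1-based)."""
    dep = _Deployment(
        deployment_id="",
        dive_index=np.array([0]),
        Y=np.log(np.array([[dive[c] for c in CONT_COLUMNS]], float)),
        B=np.array([[dive[c] for c in BIN_COLUMNS]], float),
        sex=float(_encode_sex([dive["sex"]])[0]),
        z=np.empty(0),
    )
    return float(_emission_loglik(spec, dep)[0, state - 1])


def _forward(pi, P, logE):
    """Scaled forward pass; returns loglik and normalized alpha."""
    T, N = logE.shape
    alpha = np.empty((T, N))
    ll = 0.0
    prev = pi
    for t in range(T):
        shift = logE[t].max()
        a = prev * np.exp(logE[t] - shift)
        c = a.sum()
        alpha[t] = a / c
        ll += np.log(c) + shift
        prev = alpha[t] @ P
    return ll, alpha


def _forward_backward(pi, P, logE):
    """Posteriors gamma (T,N) and summed pairwise xi (N,N), plus loglik."""
    T, N = logE.shape
    ll, alpha = _forward(pi, P, logE)
    E = np.exp(logE - logE.max(axis=1, keepdims=True))
    beta = np.empty((T, N))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        b = P @ (E[t + 1] * beta[t + 1])
        beta[t] = b / b.sum()
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        A = alpha[:-1]
        Bm = E[1:] * beta[1:]
        c = np.einsum("ti,ij,tj->t", A, P, Bm)
        xi_sum = np.einsum("ti,tj->ij", A / c[:, None], Bm) * P
    else:
        xi_sum = np.zeros((N, N))
    return ll, gamma, xi_sum


def forward_loglik(spec: HmmSpec, data: pd.DataFrame) -> float:
    """Total log-likelihood: sum of independent per-deployment chains."""
    deployments, _ = _prepare(data, spec.transition_covariate)
    total = 0.0
    for dep in deployments:
        P = transition_matrix(spec, dep.z)
        ll, _ = _forward(spec.pi, P, _emission_loglik(spec, dep))
        total += ll
    return float(total)


def count_parameters(n_states: int, n_transition_covariate_columns: int) -> int:
    """Free parameters: 16N emission + N(N-1)(1+p) transition + (N-1) initial."""
    N, p = n_states, n_transition_covariate_columns
    if N < 2:
        raise ValueError("count_parameters requires at least 2 states")
    return 16 * N + N * (N - 1) * (1 + p) + (N - 1)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion: -2 loglik + 2k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return -2.0 * loglik + 2.0 * k


@dataclass
class FitResult:
    """A converged EM fit with decoded states and diagnostics."""

    spec: HmmSpec
    loglik: float
    aic: float
    k: int
    n_restarts_converged: int
    posterior: pd.DataFrame  # deployment_id, dive_index, p_state1..N
    viterbi: dict[str, np.ndarray]  # 1-based state sequences
    em_trace: list[float]
    state_stats: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# M-step closed forms


def _weighted_sex_regression(y, sex, w):
    """Exact weighted LS of y on [1, sex] for a binary sex column."""
    w0 = w * (sex == 0.0)
    w1 = w * (sex == 1.0)
    s0, s1 = w0.sum(), w1.sum()
    if s0 > 1e-12 and s1 > 1e-12:
        m0 = (w0 * y).sum() / s0
        m1 = (w1 * y).sum() / s1
        return m0, m1 - m0
    m = (w * y).sum() / max(w.sum(), 1e-300)
    return m, 0.0


def _mstep(deployments, stats, n_states, p, levels, covariate):
    """Closed-form parameter updates from expected sufficient statistics."""
    N = n_states
    gam = np.concatenate([g for _, g, _ in stats], axis=0)  # (T_all, N)
    Y = np.concatenate([d.Y for d in deployments], axis=0)
    B = np.concatenate([d.B for d in deployments], axis=0)
    sex = np.concatenate(
        [np.full(len(d.Y), d.sex) for d in deployments]
    )
    cont_coef = np.zeros((N, 4, 2))
    cont_sd = np.zeros((N, 4))
    bin_coef = np.zeros((N, 2, 2))
    for j in range(N):
        w = gam[:, j]
        sw = max(w.sum(), 1e-300)
        for v in range(4):
            a, b = _weighted_sex_regression(Y[:, v], sex, w)
            cont_coef[j, v] = (a, b)
            mean = a + b * sex
            var = (w * (Y[:, v] - mean) ** 2).sum() / sw
            cont_sd[j, v] = max(np.sqrt(var), _SIGMA_FLOOR)
        for b_ in range(2):
            w0 = w * (sex == 0.0)
            w1 = w * (sex == 1.0)
            if w0.sum() > 1e-12 and w1.sum() > 1e-12:
                p0 = (w0 * B[:, b_]).sum() / w0.sum()
                p1 = (w1 * B[:, b_]).sum() / w1.sum()
            else:
                p0 = p1 = (w * B[:, b_]).sum() / sw
            p0 = np.clip(p0, _BERNOULLI_CLAMP, 1 - _BERNOULLI_CLAMP)
            p1 = np.clip(p1, _BERNOULLI_CLAMP, 1 - _BERNOULLI_CLAMP)
            l0, l1 = np.log(p0 / (1 - p0)), np.log(p1 / (1 - p1))
            bin_coef[j, b_] = (l0, l1 - l0)

    # transition rows: expected counts aggregated by covariate level, then
    # group-proportion MLE per level (the design is saturated)
    level_keys = sorted({tuple(d.z) for d in deployments})
    counts = {key: np.zeros((N, N)) for key in level_keys}
    for d, (_, _, xi) in zip(deployments, stats):
        counts[tuple(d.z)] += xi
    probs = {}
    for key, C in counts.items():
        C = np.maximum(C, _PROB_FLOOR)
        probs[key] = C / C.sum(axis=1, keepdims=True)
    trans_coef = _probs_to_coef(probs, N, p)

    pi = np.zeros(N)
    for _, g, _ in stats:
        pi += g[0]
    pi = np.maximum(pi, _PROB_FLOOR)
    pi /= pi.sum()
    return cont_coef, cont_sd, bin_coef, trans_coef, pi


def _probs_to_coef(probs_by_level: dict, N: int, p: int) -> np.ndarray:
    """Invert per-level transition matrices to multinomial-logit coefficients.

    Levels are keyed by their covariate column tuples; the zero tuple is the
    reference.  With saturated designs (each level a distinct unit vector)
    the inversion is exact; unit-vector levels absent from the data keep
    zero coefficients.
    """
    trans_coef = np.zeros((N, N - 1, 1 + p))
    base_key = tuple(np.zeros(p))
    if base_key in probs_by_level:
        base = probs_by_level[base_key]
    else:  # reference level unobserved: use the pooled average as intercept
        base = np.mean(list(probs_by_level.values()), axis=0)
    eta_base = np.log(base[:, 1:] / base[:, [0]])
    trans_coef[:, :, 0] = eta_base
    for c in range(p):
        key = tuple(1.0 if i == c else 0.0 for i in range(p))
        if key in probs_by_level:
            eta = np.log(probs_by_level[key][:, 1:] / probs_by_level[key][:, [0]])
            trans_coef[:, :, c + 1] = eta - eta_base
    return trans_coef


def _init_params(deployments, n_states, p, rng):
    """Random restart initialization: responsibilities from a randomized
    nearest-center split of the standardized ln-continuous channels plus
    Dirichlet noise, then one M-step."""
    N = n_states
    Y = np.concatenate([d.Y for d in deployments], axis=0)
    Z = (Y - Y.mean(axis=0)) / np.maximum(Y.std(axis=0), 1e-12)
    centers = Z[rng.choice(len(Z), size=N, replace=False)]
    dist = ((Z[:, None, :] - centers[None]) ** 2).sum(axis=2)
    onehot = np.zeros((len(Z), N))
    onehot[np.arange(len(Z)), dist.argmin(axis=1)] = 1.0
    resp = 0.85 * onehot + 0.15 * rng.dirichlet(np.ones(N), size=len(Z))
    resp /= resp.sum(axis=1, keepdims=True)
    stats = []
    i = 0
    for d in deployments:
        g = resp[i : i + len(d.Y)]
        i += len(d.Y)
        trans = rng.dirichlet(np.ones(N), size=N) * len(d.Y) / N
        stats.append((0.0, g, trans))
    return stats


def em_fit(
    data: pd.DataFrame,
    n_states: int,
    transition_covariate: str | None = None,
    n_restarts: int = 200,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    degeneracy_floor: float = 1e-3,
) -> FitResult:
    """Fit the covariate HMM by multi-restart EM; retain the best by AIC.

    Restart r uses the deterministic child seed ``SeedSequence([seed, r])``,
    so results are independent of execution order.  A restart in which some
    state's total responsibility falls below ``degeneracy_floor`` is
    discarded as degenerate; if every restart degenerates an error is
    raised.
    """
    deployments, levels = _prepare(data, transition_covariate)
    if not deployments:
        raise ValueError("no non-empty deployments")
    n_obs = sum(len(d.Y) for d in deployments)
    if n_obs < n_states:
        raise ValueError("fewer observations than states")
    p = len(deployments[0].z)
    best = None
    n_converged = 0
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        try:
            result = _em_single(
                deployments, n_states, p, levels, transition_covariate,
                rng, max_iter, tol, degeneracy_floor,
            )
        except _DegenerateRestart:
            logger.info("restart %d degenerate; discarded", r)
            continue
        n_converged += 1
        if best is None or result[0] > best[0]:
            best = result
    if best is None:
        raise RuntimeError("all EM restarts degenerate")
    ll, spec, trace, gammas = best
    k = count_parameters(n_states, p) if n_states >= 2 else 16
    post_rows = []
    paths = {}
    for d, g in zip(deployments, gammas):
        frame = pd.DataFrame(
            g, columns=[f"p_state{j + 1}" for j in range(n_states)]
        )
        frame.insert(0, "dive_index", d.dive_index)
        frame.insert(0, "deployment_id", d.deployment_id)
        post_rows.append(frame)
        paths[d.deployment_id] = _viterbi_single(
            spec.pi, transition_matrix(spec, d.z), _emission_loglik(spec, d)
        ) + 1
    posterior = pd.concat(post_rows, ignore_index=True)
    fit = FitResult(
        spec=spec,
        loglik=float(ll),
        aic=aic(ll, k),
        k=k,
        n_restarts_converged=n_converged,
        posterior=posterior,
        viterbi=paths,
        em_trace=trace,
        state_stats=_relabel_stats(deployments, gammas, n_states),
    )
    return fit


class _DegenerateRestart(Exception):
    pass


def _em_single(deployments, n_states, p, levels, covariate, rng,
               max_iter, tol, degeneracy_floor):
    N = n_states
    stats = _init_params(deployments, N, p, rng)
    cont_coef, cont_sd, bin_coef, trans_coef, pi = _mstep(
        deployments, stats, N, p, levels, covariate
    )
    spec = HmmSpec(N, cont_coef, cont_sd, bin_coef, trans_coef, pi,
                   covariate, levels)
    prev_ll = -np.inf
    trace: list[float] = []
    gammas = None
    for _ in range(max_iter):
        total_ll = 0.0
        stats = []
        gammas = []
        for d in deployments:
            P = transition_matrix(spec, d.z)
            ll, gamma, xi = _forward_backward(spec.pi, P, _emission_loglik(spec, d))
            total_ll += ll
            stats.append((ll, gamma, xi))
            gammas.append(gamma)
        trace.append(float(total_ll))
        occupancy = np.sum([g.sum(axis=0) for g in gammas], axis=0)
        if occupancy.min() < degeneracy_floor:
            raise _DegenerateRestart
        if abs(total_ll - prev_ll) < tol:
            break
        prev_ll = total_ll
        cont_coef, cont_sd, bin_coef, trans_coef, pi = _mstep(
            deployments, stats, N, p, levels, covariate
        )
        spec = HmmSpec(N, cont_coef, cont_sd, bin_coef, trans_coef, pi,
                       covariate, levels)
    return trace[-1], spec, trace, gammas


def _relabel_stats(deployments, gammas, n_states):
    """Posterior-weighted ln-depth means and slow-click rates per state."""
    g = np.concatenate(gammas, axis=0)
    lnd = np.concatenate([d.Y[:, 0] for d in deployments])
    slow = np.concatenate([d.B[:, 1] for d in deployments])
    tot = np.maximum(g.sum(axis=0), 1e-300)
    return {
        "ln_depth_mean": (g * lnd[:, None]).sum(axis=0) / tot,
        "slow_click_rate": (g * slow[:, None]).sum(axis=0) / tot,
    }


def _viterbi_single(pi, P, logE) -> np.ndarray:
    T, N = logE.shape
    logP = np.log(np.maximum(P, 1e-300))
    delta = np.log(np.maximum(pi, 1e-300)) + logE[0]
    back = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logP
        back[t] = scores.argmax(axis=0)  # argmax takes the first (lowest) index
        delta = scores.max(axis=0) + logE[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi(spec: HmmSpec, data: pd.DataFrame) -> dict[str, np.ndarray]:
    """Most probable state sequence (1-based) per deployment."""
    deployments, _ = _prepare(data, spec.transition_covariate)
    return {
        d.deployment_id: _viterbi_single(
            spec.pi, transition_matrix(spec, d.z), _emission_loglik(spec, d)
        ) + 1
        for d in deployments
    }


# ---------------------------------------------------------------------------
# Canonical state ordering


def _canonical_permutation(stats: dict) -> np.ndarray:
    depth = stats["ln_depth_mean"]
    slow = stats["slow_click_rate"]
    first = int(np.argmax(depth))
    rest = [j for j in range(len(depth)) if j != first]
    rest.sort(key=lambda j: (-slow[j], depth[j]))
    return np.array([first] + rest)


def permute_states(fit: FitResult, perm: np.ndarray) -> FitResult:
    """Relabel states by ``perm`` (new label i <- old label perm[i])."""
    spec = fit.spec
    N = spec.n_states
    p = spec.n_covariate_columns
    # permute transition structure via per-level probability matrices
    probs = {}
    base_key = tuple(np.zeros(p))
    probs[base_key] = transition_matrix(spec, np.zeros(p))[np.ix_(perm, perm)]
    for c in range(p):
        z = np.zeros(p)
        z[c] = 1.0
        probs[tuple(z)] = transition_matrix(spec, z)[np.ix_(perm, perm)]
    new_spec = replace(
        spec,
        cont_coef=spec.cont_coef[perm],
        cont_sd=spec.cont_sd[perm],
        bin_coef=spec.bin_coef[perm],
        trans_coef=_probs_to_coef(probs, N, p) if N > 1 else spec.trans_coef,
        pi=spec.pi[perm],
    )
    inv = np.empty(N, dtype=int)
    inv[perm] = np.arange(N)
    post = fit.posterior.copy()
    cols = [f"p_state{j + 1}" for j in range(N)]
    post[cols] = post[cols].to_numpy()[:, perm]
    paths = {d: inv[path - 1] + 1 for d, path in fit.viterbi.items()}
    stats = {k: v[perm] for k, v in fit.state_stats.items()}
    return replace(fit, spec=new_spec, posterior=post, viterbi=paths,
                   state_stats=stats)


def canonical_relabel(fit: FitResult) -> FitResult:
    """Deterministic state order: the deepest state first (posterior-mean
    ln max depth), remaining states by descending slow-click rate then
    ascending depth."""
    return permute_states(fit, _canonical_permutation(fit.state_stats))
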