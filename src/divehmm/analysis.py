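"""Downstream inference on decoded behavioral states.

Per-sex transition matrices from the fitted covariate HMM, sex x state
allocation tables (dive counts, cumulative seconds, time shares), the
Pearson chi-square test of sex differences in cumulative time per state,
and the linear mixed model for dive duration with Tukey-adjusted pairwise
comparisons and a compact letter display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hmm import FitResult, transition_matrix

__all__ = [
    "AllocationTable",
    "ChiSquareResult",
    "transition_report",
    "allocation_summary",
    "chisq_independence",
    "duration_model",
    "DurationModelResult",
]

logger = logging.getLogger(__name__)


@dataclass
class AllocationTable:
    """Per (sex, state) dive counts, cumulative seconds and time shares."""

    table: pd.DataFrame  # sex, state, n_dives, cum_seconds, pct_time

    def seconds_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="sex", columns="state",
                                values="cum_seconds")

    def counts_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="sex", columns="state",
                                values="n_dives")


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def transition_report(fit: FitResult) -> dict[str, np.ndarray]:
    """Fitted transition matrices per sex (requires the sex covariate)."""
    if fit.spec.transition_covariate != "sex":
        raise ValueError(
            "transition_report requires a model with the sex transition "
            f"covariate, got {fit.spec.transition_covariate!r}"
        )
    return {
        "F": transition_matrix(fit.spec, [0.0]),
        "M": transition_matrix(fit.spec, [1.0]),
    }


def allocation_summary(
    states: np.ndarray,
    durations: np.ndarray,
    sex: np.ndarray,
) -> AllocationTable:
    """Tabulate dives and cumulative seconds per (sex, state).

    Percentages are of each sex's total sampled time.  Inputs are parallel
    per-dive arrays (states 1-based, durations in seconds).
    """
    frame = pd.DataFrame({
        "state": np.asarray(states, int),
        "duration": np.asarray(durations, float),
        "sex": np.asarray(sex),
    })
    grouped = (
        frame.groupby(["sex", "state"], sort=True)
        .agg(n_dives=("state", "size"), cum_seconds=("duration", "sum"))
        .reset_index()
    )
    totals = grouped.groupby("sex")["cum_seconds"].transform("sum")
    grouped["pct_time"] = 100.0 * grouped["cum_seconds"] / totals
    return AllocationTable(grouped)


def chisq_independence(table: np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence on an R x C table.

    Applied to the cumulative-seconds matrix exactly as counts (no
    continuity correction).
    """
    table = np.asarray(table, float)
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("table has a zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p=float(res.pvalue)
    )


# ---------------------------------------------------------------------------
# Dive-duration mixed model


@dataclass
class DurationModelResult:
    anova: pd.DataFrame  # term, F, df_num, df_den, p
    pairwise: pd.DataFrame  # group1, group2, estimate, se, p_tukey
    letters: dict[str, str]  # group -> compact letter display
    lsmeans: pd.DataFrame  # group, state, sex, lsmean
    singular: bool


def duration_model(
    durations: np.ndarray,
    states: np.ndarray,
    sex: np.ndarray,
    deployment: np.ndarray,
    alpha: float = 0.05,
) -> DurationModelResult:
    """ln(duration) ~ state + sex + (1 | deployment), with Tukey contrasts.

    Fits a random-intercept linear mixed model (statsmodels MixedLM),
    reports Wald F tests per fixed-effect term, and compares the
    state x sex cell means (additive least-squares means) pairwise with
    studentized-range (Tukey) adjustment, summarized as a compact letter
    display.  A singular random-effect fit falls back to ordinary least
    squares with a warning.
    """
    import statsmodels.api as sm

    y = np.log(np.asarray(durations, float))
    state = np.asarray(states, int)
    sx = np.asarray(sex)
    dep = np.asarray(deployment)
    state_levels = np.unique(state)
    sex_levels = np.unique(sx)
    # treatment coding vs the first level of each factor
    X_cols = {"Intercept": np.ones_like(y)}
    for s in state_levels[1:]:
        X_cols[f"state[{s}]"] = (state == s).astype(float)
    for s in sex_levels[1:]:
        X_cols[f"sex[{s}]"] = (sx == s).astype(float)
    X = pd.DataFrame(X_cols)

    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=dep)
        try:
            res = model.fit(reml=True)
            singular = bool(res.cov_re.values.min() < 1e-10)
        except Exception:  # noqa: BLE001 - optimizer failure on edge data
            singular = True
        if singular:
            logger.warning("singular random-effect fit; falling back to OLS")
            res = sm.OLS(y, X).fit()

    params = res.params[X.columns] if hasattr(res.params, "__getitem__") else res.params
    cov = pd.DataFrame(res.cov_params()).loc[X.columns, X.columns].to_numpy()
    beta = np.asarray(params, float)
    df_den = max(len(y) - X.shape[1] - len(np.unique(dep)), 1)

    anova_rows = []
    for term, cols in (
        ("state", [c for c in X.columns if c.startswith("state[")]),
        ("sex", [c for c in X.columns if c.startswith("sex[")]),
    ):
        if not cols:
            continue
        idx = [X.columns.get_loc(c) for c in cols]
        C = np.zeros((len(idx), len(beta)))
        for r, i in enumerate(idx):
            C[r, i] = 1.0
        cb = C @ beta
        V = C @ cov @ C.T
        if np.linalg.norm(cb) < 1e-10:  # degenerate (e.g. constant response)
            F, p = 0.0, 1.0
        else:
            F = float(cb @ np.linalg.solve(V, cb) / len(idx))
            p = float(sps.f.sf(F, len(idx), df_den))
        anova_rows.append({"term": term, "F": F, "df_num": len(idx),
                           "df_den": df_den, "p": p})
    anova = pd.DataFrame(anova_rows)

    # least-squares means for the state x sex cells of the additive model
    groups, contrasts = [], []
    for s in state_levels:
        for g in sex_levels:
            c = np.zeros(len(beta))
            c[0] = 1.0
            if f"state[{s}]" in X.columns:
                c[X.columns.get_loc(f"state[{s}]")] = 1.0
            if f"sex[{g}]" in X.columns:
                c[X.columns.get_loc(f"sex[{g}]")] = 1.0
            groups.append(f"{s}{g}")
            contrasts.append(c)
    contrasts = np.array(contrasts)
    means = contrasts @ beta
    lsmeans = pd.DataFrame({
        "group": groups,
        "state": np.repeat(state_levels, len(sex_levels)),
        "sex": np.tile(sex_levels, len(state_levels)),
        "lsmean": means,
    })

    k = len(groups)
    pair_rows = []
    sig = {}
    for i in range(k):
        for j in range(i + 1, k):
            c = contrasts[i] - contrasts[j]
            se = float(np.sqrt(c @ cov @ c))
            diff = float(means[i] - means[j])
            q = abs(diff) / se * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, df_den))
            pair_rows.append({"group1": groups[i], "group2": groups[j],
                              "estimate": diff, "se": se, "p_tukey": p})
            sig[(groups[i], groups[j])] = p < alpha
    pairwise = pd.DataFrame(pair_rows)
    letters = _compact_letters(groups, means, sig)
    return DurationModelResult(anova, pairwise, letters, lsmeans, singular)


def _compact_letters(groups, means, significant) -> dict[str, str]:
    """Insert-and-absorb compact letter display; groups sharing a letter do
    not differ significantly.  Ties are broken by mean rank (alphabetical
    letters assigned in ascending-mean order)."""
    order = sorted(range(len(groups)), key=lambda i: (means[i], groups[i]))
    letter_sets: list[set[int]] = []
    for i in order:
        placed = False
        for s in letter_sets:
            if all(not _sig(significant, groups[i], groups[j]) for j in s):
                s.add(i)
                placed = True
        if not placed:
            letter_sets.append({i})
    # absorb redundant sets
    letter_sets = [
        s for a, s in enumerate(letter_sets)
        if not any(s < t for b, t in enumerate(letter_sets) if a != b)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for i in sorted(s):
            out[groups[i]] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def _sig(significant, a, b) -> bool:
    return significant.get((a, b), significant.get((b, a), False))
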