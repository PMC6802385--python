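"""AIC model selection over the state-count x transition-covariate grid.

Twelve candidate models: 3, 4 or 5 latent states crossed with a transition
covariate of sex, age class, year, or none.  Each cell is fitted by
multi-restart EM and the grid is compared by AIC; the selected model is the
overall AIC minimum, with ties broken toward fewer states and then fewer
covariate columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import FitResult, aic, count_parameters, em_fit

__all__ = [
    "ModelGridResult",
    "fit_model_grid",
    "select_best",
    "delta_aic_from_logliks",
    "COVARIATE_COLUMNS",
]

logger = logging.getLogger(__name__)

# columns contributed to the transition design by each covariate choice
COVARIATE_COLUMNS = {None: 0, "sex": 1, "age_class": 1, "year": 2}


@dataclass
class ModelGridResult:
    """Grid table (one row per fitted model) plus the selected fit."""

    table: pd.DataFrame  # n_states, trans_cov, loglik, k, aic, delta_aic
    fits: dict[tuple[int, str | None], FitResult]
    best_key: tuple[int, str | None]

    @property
    def best_model(self) -> FitResult:
        return self.fits[self.best_key]


def fit_model_grid(
    features: pd.DataFrame,
    states: tuple[int, ...] = (3, 4, 5),
    covariates: tuple[str | None, ...] = (None, "sex", "age_class", "year"),
    n_restarts: int = 200,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> ModelGridResult:
    """Fit every (n_states, covariate) cell and tabulate AIC differences.

    Cell seeds are derived deterministically from the master seed by the
    cell's position in the grid, so cells may be computed in any order.
    Cells in which every restart degenerates are reported with NaN
    log-likelihood and excluded from the AIC minimum.
    """
    fits: dict[tuple[int, str | None], FitResult] = {}
    rows = []
    for ci, cov in enumerate(covariates):
        for si, n in enumerate(states):
            cell_seed = int(
                np.random.SeedSequence([seed, ci * len(states) + si])
                .generate_state(1)[0] % (2**31)
            )
            try:
                fit = em_fit(
                    features, n, cov, n_restarts=n_restarts,
                    max_iter=max_iter, tol=tol, seed=cell_seed,
                )
            except RuntimeError as exc:
                logger.warning("grid cell (%d, %s) failed: %s", n, cov, exc)
                rows.append({"n_states": n, "trans_cov": cov or "null",
                             "loglik": np.nan, "k": np.nan, "aic": np.nan})
                continue
            fits[(n, cov)] = fit
            rows.append({"n_states": n, "trans_cov": cov or "null",
                         "loglik": fit.loglik, "k": fit.k, "aic": fit.aic})
    table = pd.DataFrame(rows)
    best_aic = table["aic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    table = table.sort_values(
        ["n_states", "delta_aic"], ascending=[False, True]
    ).reset_index(drop=True)
    best_key = select_best_key(table)
    return ModelGridResult(table=table, fits=fits, best_key=best_key)


def select_best_key(table: pd.DataFrame) -> tuple[int, str | None]:
    """AIC-minimal grid row; ties go to fewer states, then fewer columns."""
    valid = table.dropna(subset=["aic"])
    if valid.empty:
        raise ValueError("no successfully fitted grid cells")
    best = valid[valid["aic"] == valid["aic"].min()].copy()
    best["p"] = best["trans_cov"].map(
        lambda c: COVARIATE_COLUMNS[None if c == "null" else c]
    )
    best = best.sort_values(["n_states", "p"]).iloc[0]
    cov = None if best["trans_cov"] == "null" else best["trans_cov"]
    return int(best["n_states"]), cov


def select_best(grid: ModelGridResult) -> FitResult:
    """The selected model of a fitted grid."""
    return grid.best_model


def delta_aic_from_logliks(
    ll_a: float, k_a: int, ll_b: float, k_b: int
) -> float:
    """AIC difference of model a relative to model b on shared data."""
    return aic(ll_a, k_a) - aic(ll_b, k_b)
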