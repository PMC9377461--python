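"""Multiple imputation by chained equations (MICE).

Produces ``m`` completed copies of a cohort with missing covariate cells.
Each imputation initialises missing cells by sampling observed values, then
sweeps the incomplete columns ``n_cycles`` times, re-imputing every column
from a model fitted on the currently-completed remaining covariates plus the
fall indicator:

* binary columns — logistic regression; missing cells drawn Bernoulli from
  the fitted probabilities, so the imputed domain stays {0, 1};
* continuous columns — linear regression followed by predictive mean
  matching (PMM): each missing cell receives the observed value of one of
  the ``k`` donors whose fitted means are closest to its own fitted mean,
  which keeps imputations inside the observed support.

Observed cells are never modified. Per-imputation seeds are spawned
deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .synthetic_cohort import Cohort

__all__ = ["ImputationSpec", "mice_impute", "pool_scalar_over_imputations"]


@dataclass(frozen=True)
class ImputationSpec:
    """Settings of the chained-equations run.

    ``m`` completed data sets (default 20), ``n_cycles`` sweeps over the
    incomplete columns per data set, and ``pmm_donors`` nearest-mean donors
    for continuous columns.
    """

    m: int = 20
    n_cycles: int = 10
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be at least 1")


def _is_binary(values: np.ndarray) -> bool:
    finite = values[np.isfinite(values)]
    return np.all((finite == 0.0) | (finite == 1.0))


def _impute_once(
    frame: pd.DataFrame,
    mask: np.ndarray,
    fall: np.ndarray,
    spec: ImputationSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    values = frame.to_numpy(dtype=float).copy()
    n, p = values.shape
    col_missing = mask.sum(axis=0)
    binary = [_is_binary(values[~mask[:, j], j]) for j in range(p)]

    # Initialise missing cells from the observed marginal of each column.
    for j in np.flatnonzero(col_missing):
        obs = values[~mask[:, j], j]
        values[mask[:, j], j] = rng.choice(obs, size=int(col_missing[j]), replace=True)

    order = np.argsort(col_missing, kind="stable")
    order = [j for j in order if col_missing[j] > 0]

    for _ in range(spec.n_cycles):
        for j in order:
            miss = mask[:, j]
            others = np.delete(np.arange(p), j)
            design = np.column_stack([values[:, others], fall.astype(float)])
            x_obs, y_obs = design[~miss], values[~miss, j]
            x_mis = design[miss]
            if binary[j]:
                if y_obs.min() == y_obs.max():
                    prob = np.full(x_mis.shape[0], float(y_obs[0]))
                else:
                    model = LogisticRegression(max_iter=200, C=100.0)
                    model.fit(x_obs, y_obs)
                    prob = model.predict_proba(x_mis)[:, 1]
                values[miss, j] = (rng.uniform(size=prob.shape[0]) < prob).astype(float)
            else:
                a = np.column_stack([np.ones(x_obs.shape[0]), x_obs])
                beta, *_ = np.linalg.lstsq(a, y_obs, rcond=None)
                fit_obs = a @ beta
                fit_mis = np.column_stack([np.ones(x_mis.shape[0]), x_mis]) @ beta
                values[miss, j] = _pmm_draw(fit_obs, y_obs, fit_mis, spec.pmm_donors, rng)

    return pd.DataFrame(values, columns=frame.columns, index=frame.index)


def _pmm_draw(
    fitted_obs: np.ndarray,
    y_obs: np.ndarray,
    fitted_mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive mean matching: for each target fitted value, draw one of
    the k observed cases with the nearest fitted values and return its
    observed outcome."""
    order = np.argsort(fitted_obs, kind="stable")
    sorted_fit = fitted_obs[order]
    sorted_y = y_obs[order]
    n_obs = sorted_fit.shape[0]
    k = min(k, n_obs)
    pos = np.searchsorted(sorted_fit, fitted_mis)
    out = np.empty(fitted_mis.shape[0])
    for i, (f, q) in enumerate(zip(fitted_mis, pos)):
        lo = max(0, q - k)
        hi = min(n_obs, q + k)
        window = np.arange(lo, hi)
        nearest = window[np.argsort(np.abs(sorted_fit[window] - f), kind="stable")[:k]]
        out[i] = sorted_y[rng.choice(nearest)]
    return out


def mice_impute(cohort: Cohort, spec: ImputationSpec) -> list[Cohort]:
    """Run chained-equations imputation and return ``m`` completed cohorts.

    Raises ``ValueError`` if a column has no observed value (un-imputable)
    or no column is fully observed.
    """
    mask = cohort.missing_mask
    frame = cohort.covariates
    col_missing = mask.sum(axis=0)
    fully_missing = np.flatnonzero(col_missing == cohort.n)
    if fully_missing.size:
        bad = [cohort.covariate_names[j] for j in fully_missing]
        raise ValueError(f"columns with no observed values cannot be imputed: {bad}")
    if not np.any(col_missing == 0):
        raise ValueError("at least one fully observed column is required")

    if not mask.any():
        return [
            Cohort(
                covariates=frame.copy(),
                fall=cohort.fall.copy(),
                los=cohort.los.copy(),
                risk_score=None if cohort.risk_score is None else cohort.risk_score.copy(),
                config=cohort.config,
            )
            for _ in range(spec.m)
        ]

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.m)
    completed = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        filled = _impute_once(frame, mask, cohort.fall, spec, rng)
        completed.append(
            Cohort(
                covariates=filled,
                fall=cohort.fall.copy(),
                los=cohort.los.copy(),
                risk_score=None if cohort.risk_score is None else cohort.risk_score.copy(),
                config=cohort.config,
            )
        )
    return completed


def pool_scalar_over_imputations(estimates: Sequence[float]) -> float:
    """Arithmetic mean of per-imputation point estimates."""
    estimates = np.asarray(list(estimates), dtype=float)
    if estimates.size == 0:
        raise ValueError("cannot pool an empty sequence of estimates")
    return float(estimates.mean())
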