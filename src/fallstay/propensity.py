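"""Propensity-score estimation, matching, balance diagnostics and ATET.

The causal chain mirrors the standard observational workflow for a rare
binary exposure (here, an in-hospital fall) with a continuous outcome (the
length of stay):

1. fit a maximum-likelihood logistic model of exposure on the covariates
   (the propensity score e(x));
2. pair every exposed subject with the unexposed subject of nearest score,
   with replacement, ties to the lowest control id;
3. check covariate balance via standardized differences before and after
   matching (|d| < 0.1 conventionally indicates balance);
4. estimate the average treatment effect on the treated (ATET) as the mean
   treated-minus-matched-control outcome difference, with a percentile
   bootstrap CI over the matched pairs.

With multiply-imputed data the whole chain runs per completed data set and
point estimates are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .classifier_eval import auc

__all__ = [
    "PropensityFit",
    "MatchedPairs",
    "AtetEstimate",
    "fit_propensity",
    "match_nn_replacement",
    "standardized_difference",
    "standardized_difference_from_moments",
    "estimate_atet",
    "balance_report",
    "pooled_matched_analysis",
]


@dataclass
class PropensityFit:
    """Fitted logistic propensity model."""

    coefficients: pd.Series  # includes 'const'
    scores: np.ndarray  # fitted P(treated | x), in (0, 1)
    in_sample_auc: float


@dataclass
class MatchedPairs:
    """1:1 nearest-neighbor matches; controls may repeat (replacement)."""

    treated: np.ndarray  # subject indices, one per treated unit
    control: np.ndarray  # matched control index per treated unit

    def __post_init__(self) -> None:
        self.treated = np.asarray(self.treated, dtype=int)
        self.control = np.asarray(self.control, dtype=int)
        if self.treated.shape != self.control.shape:
            raise ValueError("treated and control index arrays must align")
        if np.unique(self.treated).shape[0] != self.treated.shape[0]:
            raise ValueError("every treated subject must appear exactly once")

    @property
    def n_pairs(self) -> int:
        return int(self.treated.shape[0])

    def pair_diffs(self, outcomes: np.ndarray) -> np.ndarray:
        """Treated-minus-control outcome per pair."""
        outcomes = np.asarray(outcomes, dtype=float)
        return outcomes[self.treated] - outcomes[self.control]


@dataclass(frozen=True)
class AtetEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def _design(covariates: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    x = np.asarray(covariates, dtype=float)
    return x, [f"x{j}" for j in range(x.shape[1])]


def fit_propensity(
    covariates: pd.DataFrame | np.ndarray, treatment: Sequence[int]
) -> PropensityFit:
    """Maximum-likelihood logistic regression of treatment on covariates.

    Requires a complete (post-imputation) covariate matrix with both classes
    present. Raises on rank-deficient designs (naming offending columns) and
    on perfect separation.
    """
    x, names = _design(covariates)
    y = np.asarray(treatment, dtype=float)
    if np.isnan(x).any():
        raise ValueError("covariates contain missing cells; impute first")
    if y.min() == y.max():
        raise ValueError("need at least one treated and one control subject")

    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [
            (["const"] + names)[j]
            for j in np.flatnonzero(diag < 1e-8 * diag.max())
        ]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")

    try:
        result = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except PerfectSeparationError as err:  # pragma: no cover - data dependent
        raise ValueError(f"perfect separation in propensity model: {err}") from err
    if not np.all(np.isfinite(result.params)):
        raise ValueError("propensity fit diverged (possible separation)")

    scores = np.asarray(result.predict(design), dtype=float)
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    coef = pd.Series(result.params, index=["const"] + names)
    return PropensityFit(
        coefficients=coef, scores=scores, in_sample_auc=auc(scores, y.astype(int))
    )


def match_nn_replacement(
    scores: Sequence[float],
    treatment: Sequence[int],
    caliper: float | None = None,
) -> MatchedPairs:
    """Pair each treated subject with the control of nearest score.

    Controls are reusable (matching with replacement); equidistant controls
    resolve to the lowest control id, making the result deterministic and
    independent of input permutation. With a ``caliper`` (score units),
    treated subjects whose nearest control is farther than the caliper are
    dropped.
    """
    scores = np.asarray(scores, dtype=float)
    treatment = np.asarray(treatment)
    t_idx = np.flatnonzero(treatment == 1)
    c_idx = np.flatnonzero(treatment == 0)
    if c_idx.shape[0] == 0:
        raise ValueError("no control subjects available for matching")

    order = np.argsort(scores[c_idx], kind="stable")
    c_sorted = c_idx[order]
    s_sorted = scores[c_sorted]
    # Collapse equal scores; the first id per group is the minimum because
    # the stable sort preserves ascending original indices within ties.
    uniq, starts = np.unique(s_sorted, return_index=True)
    min_id = c_sorted[starts]

    t_scores = scores[t_idx]
    pos = np.searchsorted(uniq, t_scores)
    left = np.clip(pos - 1, 0, uniq.shape[0] - 1)
    right = np.clip(pos, 0, uniq.shape[0] - 1)
    d_left = np.abs(t_scores - uniq[left])
    d_right = np.abs(uniq[right] - t_scores)

    take_left = (d_left < d_right) | (
        (d_left == d_right) & (min_id[left] <= min_id[right])
    )
    chosen = np.where(take_left, min_id[left], min_id[right])
    dist = np.minimum(d_left, d_right)

    if caliper is not None:
        keep = dist <= caliper
        t_idx, chosen = t_idx[keep], chosen[keep]
    return MatchedPairs(treated=t_idx, control=chosen)


def standardized_difference_from_moments(
    mean_t: float, sd_t: float, mean_c: float, sd_c: float
) -> float:
    """Two-sample Cohen-style d with averaged variances:
    (mean_t - mean_c) / sqrt((var_t + var_c) / 2)."""
    denom = np.sqrt((sd_t**2 + sd_c**2) / 2.0)
    diff = mean_t - mean_c
    if denom == 0:
        if diff == 0:
            return 0.0
        raise ValueError("degenerate input: zero variances with unequal means")
    return float(diff / denom)


def standardized_difference(
    treated_values: Sequence[float], control_values: Sequence[float]
) -> float:
    """Standardized mean difference between two samples (ddof=1 variances).

    The same formula serves binary columns, where the sample variance is the
    p(1-p) form up to the n/(n-1) factor.
    """
    t = np.asarray(treated_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both samples must be non-empty")
    sd_t = float(np.std(t, ddof=1)) if t.size > 1 else 0.0
    sd_c = float(np.std(c, ddof=1)) if c.size > 1 else 0.0
    return standardized_difference_from_moments(
        float(t.mean()), sd_t, float(c.mean()), sd_c
    )


def estimate_atet(
    pairs: MatchedPairs,
    outcomes: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> AtetEstimate:
    """ATET from matched pairs with a percentile-bootstrap 95% CI.

    The point estimate is the mean pair difference, identically
    mean(treated outcome) - mean(matched control outcome). The bootstrap
    resamples treated units together with their matched controls.
    """
    if pairs.n_pairs == 0:
        raise ValueError("no matched pairs")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    diffs = pairs.pair_diffs(np.asarray(outcomes, dtype=float))
    point = float(diffs.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diffs.shape[0], size=(n_boot, diffs.shape[0]))
    boot_means = diffs[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    lo, hi = min(float(lo), point), max(float(hi), point)
    return AtetEstimate(point=point, ci_low=lo, ci_high=hi, n_pairs=pairs.n_pairs)


def balance_report(
    covariates: pd.DataFrame,
    treatment: Sequence[int],
    pairs: MatchedPairs,
) -> pd.DataFrame:
    """Standardized differences per covariate before and after matching.

    Before matching: all treated vs all controls. After matching: treated vs
    matched controls, counting reused controls once per use.
    """
    treatment = np.asarray(treatment)
    x = covariates.to_numpy(dtype=float)
    t_all = x[treatment == 1]
    c_all = x[treatment == 0]
    t_matched = x[pairs.treated]
    c_matched = x[pairs.control]
    rows = []
    for j, name in enumerate(covariates.columns):
        rows.append(
            {
                "covariate": name,
                "std_diff_before": standardized_difference(t_all[:, j], c_all[:, j]),
                "std_diff_after": standardized_difference(
                    t_matched[:, j], c_matched[:, j]
                ),
            }
        )
    return pd.DataFrame(rows)


def pooled_matched_analysis(
    imputed_covariates: Sequence[pd.DataFrame],
    treatment: Sequence[int],
    outcomes: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    caliper: float | None = None,
) -> dict:
    """Run fit -> match -> balance -> ATET on each imputed data set and
    average the results (point estimates and CI endpoints arithmetically,
    balance per covariate).

    Returns a dict with keys ``atet`` (pooled :class:`AtetEstimate`),
    ``balance`` (pooled DataFrame), ``fits``, ``pairs`` and
    ``per_imputation_atet``.
    """
    treatment = np.asarray(treatment)
    outcomes = np.asarray(outcomes, dtype=float)
    fits, all_pairs, atets, balances = [], [], [], []
    for i, cov in enumerate(imputed_covariates):
        fit = fit_propensity(cov, treatment)
        pairs = match_nn_replacement(fit.scores, treatment, caliper=caliper)
        est = estimate_atet(pairs, outcomes, n_boot=n_boot, seed=seed + i)
        fits.append(fit)
        all_pairs.append(pairs)
        atets.append(est)
        balances.append(balance_report(cov, treatment, pairs))

    pooled = AtetEstimate(
        point=float(np.mean([a.point for a in atets])),
        ci_low=float(np.mean([a.ci_low for a in atets])),
        ci_high=float(np.mean([a.ci_high for a in atets])),
        n_pairs=int(round(np.mean([a.n_pairs for a in atets]))),
    )
    balance = balances[0][["covariate"]].copy()
    balance["std_diff_before"] = np.mean(
        [b["std_diff_before"].to_numpy() for b in balances], axis=0
    )
    balance["std_diff_after"] = np.mean(
        [b["std_diff_after"].to_numpy() for b in balances], axis=0
    )
    return {
        "atet": pooled,
        "balance": balance,
        "fits": fits,
        "pairs": all_pairs,
        "per_imputation_atet": atets,
    }
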