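"""Synthetic inpatient cohorts for fall-risk causal analysis.

Emulates the statistical structure of an elderly-inpatient cohort in which
falls both depend on baseline covariates and extend the hospital stay:

* one age covariate (rescaled to [0, 1]) plus ``K`` binary covariates with
  staggered prevalences, mimicking diagnosis / care-need / lab / drug flags;
* a logistic fall model on those covariates, intercept calibrated so the
  empirical fall prevalence hits a configurable target (~2.4% by default);
* right-skewed (lognormal) baseline length of stay whose log-mean shares the
  fall model's linear predictor, so fall-prone patients also stay longer —
  the confounding that motivates propensity matching;
* an additive extension of stay (the true ATET, in days) added to fallen
  subjects only;
* optional block-wise missingness (MCAR or MAR) on covariates; and
* optional binormal classifier risk scores at a configurable AUC.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

__all__ = [
    "CohortConfig",
    "Cohort",
    "default_covariate_prevalences",
    "default_fall_coefficients",
    "default_missingness_rates",
    "generate_cohort",
    "apply_missingness",
    "generate_risk_scores",
]

#: Variance of the fall-model linear predictor that puts the in-sample AUC of
#: the true propensity score near 0.73 for a rare outcome: with lp ~ N(0, v),
#: cases are tilted to N(v, v), giving AUC = Phi(sqrt(v/2)).
_TARGET_LP_VARIANCE = 2.0 * float(ndtri(0.73)) ** 2


def default_covariate_prevalences(n_binary: int) -> np.ndarray:
    """Marginal prevalences for the binary covariates, staggered 5%–50%."""
    return np.linspace(0.05, 0.50, n_binary)


def default_fall_coefficients(
    n_binary: int, prevalences: np.ndarray | None = None
) -> np.ndarray:
    """Log-odds coefficients (age first, then binaries) for the fall model.

    Signs alternate and magnitudes taper so that some covariates raise and
    some lower fall risk; the whole vector is scaled so the linear predictor
    variance lands on the value that yields a propensity-model AUC near
    0.73 under the default covariate distribution.
    """
    if prevalences is None:
        prevalences = default_covariate_prevalences(n_binary)
    j = np.arange(n_binary)
    base = np.concatenate(
        [[1.0], np.where(j % 2 == 0, 1.0, -1.0) * (0.3 + 0.7 * j / max(n_binary - 1, 1))]
    )
    var_x = np.concatenate([[1.0 / 12.0], prevalences * (1.0 - prevalences)])
    scale = np.sqrt(_TARGET_LP_VARIANCE / float(np.sum(base**2 * var_x)))
    return base * scale


def default_missingness_rates(n_binary: int) -> dict[str, float]:
    """Block-wise missingness rates: a lab-like block at 19.7%, a
    prescription-like block at 8.3%, everything else fully observed."""
    rates: dict[str, float] = {}
    lab = range(max(n_binary - 16, 0), max(n_binary - 8, 0))
    drugs = range(max(n_binary - 8, 0), n_binary)
    for j in lab:
        rates[f"x{j + 1:02d}"] = 0.197
    for j in drugs:
        rates[f"x{j + 1:02d}"] = 0.083
    return rates


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_subjects : int
        Number of hospitalizations to simulate.
    n_binary_covariates : int
        Number of binary covariates beside the age covariate (default 48,
        for 49 covariates in total).
    age_range : tuple of float
        Age span in years; ages are stored rescaled to [0, 1].
    fall_model_coefficients : ndarray or None
        Log-odds per covariate, age first. ``None`` selects the calibrated
        defaults.
    target_prevalence : float
        Target empirical fall prevalence in (0, 1).
    true_atet : float
        Additive extension of stay (days) applied to fallen subjects.
    baseline_los_mean, baseline_los_sd : float
        Mean and SD (days) of the marginal baseline length-of-stay
        distribution (lognormal).
    los_confounding_sd : float
        SD on the log-stay scale contributed by the (standardized) fall
        linear predictor; 0 switches confounding off.
    missingness_rates : mapping or None
        Per-column missingness rates for :func:`apply_missingness`.
    score_auc : float or None
        Target AUC of the generated binormal risk scores; ``None`` skips
        score generation.
    seed : int
        Master seed; all randomness derives from it.
    """

    n_subjects: int = 72_314
    n_binary_covariates: int = 48
    age_range: tuple[float, float] = (65.0, 99.0)
    fall_model_coefficients: np.ndarray | None = None
    target_prevalence: float = 0.024
    true_atet: float = 17.8
    baseline_los_mean: float = 10.6
    baseline_los_sd: float = 6.8
    los_confounding_sd: float = 0.25
    missingness_rates: Mapping[str, float] | None = None
    score_auc: float | None = 0.851
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.true_atet < 0.0:
            raise ValueError("true_atet must be non-negative")
        if self.score_auc is not None and not 0.5 <= self.score_auc < 1.0:
            raise ValueError("score_auc must lie in [0.5, 1)")
        if self.baseline_los_mean <= 0 or self.baseline_los_sd <= 0:
            raise ValueError("baseline stay mean and SD must be positive")
        if self.missingness_rates is not None:
            for name, rate in self.missingness_rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"missingness rate for {name!r} outside [0, 1]")
        if self.fall_model_coefficients is not None:
            coef = np.asarray(self.fall_model_coefficients, dtype=float)
            if not np.all(np.isfinite(coef)):
                raise ValueError("fall_model_coefficients must be finite")
            if coef.shape != (self.n_binary_covariates + 1,):
                raise ValueError(
                    "fall_model_coefficients must have length n_binary_covariates + 1"
                )

    def covariate_names(self) -> list[str]:
        return ["age_scaled"] + [f"x{j + 1:02d}" for j in range(self.n_binary_covariates)]


@dataclass(eq=False)
class Cohort:
    """One simulated (or loaded) cohort.

    ``covariates`` holds the *true* values; ``missing_mask`` marks cells that
    are unobserved. :meth:`observed` yields the analysis view with NaN at
    masked cells.
    """

    covariates: pd.DataFrame
    fall: np.ndarray
    los: np.ndarray
    risk_score: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.covariates)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.covariates.shape, dtype=bool)
        self.fall = np.asarray(self.fall, dtype=np.int8)
        self.los = np.asarray(self.los, dtype=float)
        if self.fall.shape != (n,) or self.los.shape != (n,):
            raise ValueError("fall and los must be one value per subject")
        if self.missing_mask.shape != self.covariates.shape:
            raise ValueError("missing_mask must align with covariates")
        if np.any(self.los <= 0):
            raise ValueError("length of stay must be positive")

    @property
    def n(self) -> int:
        return len(self.covariates)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def observed(self) -> pd.DataFrame:
        """Covariates with NaN in place of masked (missing) cells."""
        frame = self.covariates.copy()
        frame[self.missing_mask] = np.nan
        return frame

    def equals(self, other: "Cohort") -> bool:
        return (
            self.covariates.equals(other.covariates)
            and np.array_equal(self.fall, other.fall)
            and np.array_equal(self.los, other.los)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and (
                (self.risk_score is None and other.risk_score is None)
                or (
                    self.risk_score is not None
                    and other.risk_score is not None
                    and np.allclose(self.risk_score, other.risk_score, equal_nan=True)
                )
            )
        )


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Solve mean(expit(b0 + lp)) = target for the intercept b0."""

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + lp))) - target

    lo, hi = -30.0, 10.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            "prevalence calibration failed: target unreachable on the "
            "intercept search interval [-30, 10]"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a cohort under ``config``.

    Falls follow a logistic model on the covariates with the intercept
    calibrated against the realized covariate draw; baseline stay is
    lognormal with the covariate effect on the log scale, and fallen
    subjects get ``true_atet`` extra days.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_subjects, config.n_binary_covariates

    prevalences = default_covariate_prevalences(k)
    age = rng.uniform(0.0, 1.0, size=n)
    binaries = (rng.uniform(size=(n, k)) < prevalences).astype(float)
    x = np.column_stack([age, binaries])
    names = config.covariate_names()

    coef = config.fall_model_coefficients
    if coef is None:
        coef = default_fall_coefficients(k, prevalences)
    coef = np.asarray(coef, dtype=float)

    lp = x @ coef
    intercept = _calibrate_intercept(lp, config.target_prevalence)
    fall = (rng.uniform(size=n) < expit(intercept + lp)).astype(np.int8)

    mu, sigma = _lognormal_params(config.baseline_los_mean, config.baseline_los_sd)
    c = min(config.los_confounding_sd, 0.95 * sigma)
    lp_sd = float(np.std(lp))
    conf = c * (lp - lp.mean()) / lp_sd if (c > 0 and lp_sd > 0) else 0.0
    noise_sd = float(np.sqrt(sigma**2 - (c if lp_sd > 0 else 0.0) ** 2))
    los = np.exp(mu + conf + noise_sd * rng.standard_normal(n))
    los = los + config.true_atet * fall

    score = None
    if config.score_auc is not None:
        score = generate_risk_scores(
            fall, config.score_auc, seed=int(rng.integers(0, 2**31 - 1))
        )

    frame = pd.DataFrame(x, columns=names)
    return Cohort(covariates=frame, fall=fall, los=los, risk_score=score, config=config)


def apply_missingness(
    cohort: Cohort,
    rates: Mapping[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
) -> Cohort:
    """Return a copy of ``cohort`` with additional cells masked as missing.

    Under MCAR each cell of a rated column is masked independently with its
    column rate; under MAR the masking probability depends only on the
    always-observed age covariate and fall indicator (logistic in both, with
    the intercept calibrated so the column-wise expected rate is preserved).
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be 'MCAR' or 'MAR'")
    rng = np.random.default_rng(seed)
    mask = cohort.missing_mask.copy()
    names = cohort.covariate_names
    age = cohort.covariates["age_scaled"].to_numpy()
    fall = cohort.fall.astype(float)

    for name, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {name!r} outside [0, 1]")
        if name not in names:
            raise KeyError(f"unknown covariate {name!r}")
        col = names.index(name)
        if rate == 0.0:
            continue
        if rate == 1.0:
            mask[:, col] = True
            continue
        if mechanism == "MCAR":
            prob = np.full(cohort.n, rate)
        else:
            lp = 1.2 * age + 0.8 * fall
            alpha = _calibrate_intercept(lp, rate)
            prob = expit(alpha + lp)
        mask[:, col] |= rng.uniform(size=cohort.n) < prob

    return Cohort(
        covariates=cohort.covariates.copy(),
        fall=cohort.fall.copy(),
        los=cohort.los.copy(),
        risk_score=None if cohort.risk_score is None else cohort.risk_score.copy(),
        missing_mask=mask,
        config=cohort.config,
    )


def generate_risk_scores(
    labels: Sequence[int] | np.ndarray, target_auc: float, seed: int = 0
) -> np.ndarray:
    """Binormal classifier scores with expected AUC ``target_auc``.

    Non-events are standard normal; events are shifted by
    delta = sqrt(2) * Phi^{-1}(AUC) with equal unit variance, the classical
    equal-variance binormal ROC model.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must lie in [0.5, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    delta = float(np.sqrt(2.0) * ndtri(target_auc))
    scores = rng.standard_normal(labels.shape[0])
    scores[labels == 1] += delta
    return scores
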