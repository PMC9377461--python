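"""Decision-analytic model of prediction-triggered fall prevention.

Converts a fall-prediction confusion matrix plus stay/cost parameters into
hospital days saved and Yen saved per day of intervention. The accounting,
for a scenario with effect estimate ``A`` (days of stay attributable to a
fall, the ATET) and prevention rate ``r``:

* Interventions run for every predicted-positive case for its whole stay.
  Prevented true positives stay ``L_f - A`` days (their counterfactual,
  unfallen stay), unprevented true positives stay ``L_f``, and false
  positives stay ``L_u``; the sum is the intervention-day denominator D.
* ``r * TP * A`` days of stay are saved; the false negatives' potential
  saving ``r * FN * A`` is lost.
* Per-day quantities divide by D; costs multiply by the daily cost of a
  hospital bed.

``treat_all_matrix`` gives the no-model baseline (intervene on everyone),
and ``policy_sweep`` traces the savings curve over classifier cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier_eval import ConfusionMatrix, confusion_at_threshold

__all__ = [
    "StayParameters",
    "Scenario",
    "ScenarioResult",
    "round_half_up",
    "counterfactual_stay",
    "evaluate_scenario",
    "treat_all_matrix",
    "scenario_table",
    "policy_sweep",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (report rounding; 0.0005 -> 0.001 at 3 dp)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StayParameters:
    """Mean stays (days) of fallen/unfallen cases and the daily bed cost."""

    mean_los_fallen: float = 30.3
    mean_los_unfallen: float = 10.6
    daily_cost: float = 40_000.0

    def __post_init__(self) -> None:
        if min(self.mean_los_fallen, self.mean_los_unfallen, self.daily_cost) <= 0:
            raise ValueError("stay and cost parameters must be positive")
        if self.mean_los_fallen <= self.mean_los_unfallen:
            raise ValueError("fallen mean stay must exceed unfallen mean stay")


@dataclass(frozen=True)
class Scenario:
    """An (ATET, prevention rate) assumption for the intervention."""

    atet: float
    prevention_rate: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.atet <= 0:
            raise ValueError("atet must be positive")
        if not 0.0 <= self.prevention_rate <= 1.0:
            raise ValueError("prevention_rate must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioResult:
    """Day and cost accounting of one scenario (unrounded arithmetic)."""

    intervention_days: float
    reduced_days: float
    lost_days: float
    reduced_per_day: float
    lost_per_day: float
    net_per_day: float
    cost_per_day: float

    @property
    def net_days(self) -> float:
        return self.reduced_days - self.lost_days


def counterfactual_stay(params: StayParameters, atet: float) -> float:
    """Mean stay the fallen cases would have had without the fall."""
    if not 0.0 <= atet < params.mean_los_fallen:
        raise ValueError("atet must lie in [0, mean_los_fallen)")
    return params.mean_los_fallen - atet


def evaluate_scenario(
    cm: ConfusionMatrix, params: StayParameters, scenario: Scenario
) -> ScenarioResult:
    """Per-intervention-day savings of intervening on predicted positives."""
    a, r = scenario.atet, scenario.prevention_rate
    l_f, l_u = params.mean_los_fallen, params.mean_los_unfallen
    counterfactual = counterfactual_stay(params, a)
    days = (
        r * cm.tp * counterfactual + (1.0 - r) * cm.tp * l_f + cm.fp * l_u
    )
    if days == 0:
        raise ValueError("empty intervention set: no predicted-positive days")
    reduced = r * cm.tp * a
    lost = r * cm.fn * a
    net = reduced - lost
    return ScenarioResult(
        intervention_days=days,
        reduced_days=reduced,
        lost_days=lost,
        reduced_per_day=reduced / days,
        lost_per_day=lost / days,
        net_per_day=net / days,
        cost_per_day=net / days * params.daily_cost,
    )


def treat_all_matrix(n_fallen: int, n_unfallen: int) -> ConfusionMatrix:
    """Confusion matrix of intervening on every case (no prediction model)."""
    return ConfusionMatrix(tp=n_fallen, fp=n_unfallen, fn=0, tn=0)


def scenario_table(
    cm: ConfusionMatrix, params: StayParameters, scenarios: Sequence[Scenario]
) -> pd.DataFrame:
    """Evaluate each scenario in order; one row per scenario."""
    rows = []
    for i, sc in enumerate(scenarios):
        res = evaluate_scenario(cm, params, sc)
        rows.append(
            {
                "scenario": sc.name or f"Scenario {i + 1}",
                "atet": sc.atet,
                "prevention_rate": sc.prevention_rate,
                "reduced_per_day": res.reduced_per_day,
                "lost_per_day": res.lost_per_day,
                "net_per_day": res.net_per_day,
                "cost_per_day": res.cost_per_day,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "atet",
            "prevention_rate",
            "reduced_per_day",
            "lost_per_day",
            "net_per_day",
            "cost_per_day",
        ],
    )


def policy_sweep(
    scores: Sequence[float],
    labels: Sequence[int],
    params: StayParameters,
    scenarios: Sequence[Scenario],
    min_sensitivity: float = 0.5,
) -> pd.DataFrame:
    """Savings across classifier cutoffs, one row per (cutoff, scenario).

    Candidate cutoffs are the distinct observed scores plus a -inf sentinel,
    whose all-positive classification is the treat-all endpoint. Rows with
    sensitivity below ``min_sensitivity`` are dropped; output is sorted by
    sensitivity then scenario order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[-np.inf], np.unique(scores)])
    n_events = int(np.sum(labels == 1))
    rows = []
    for thr in thresholds:
        cm = confusion_at_threshold(scores, labels, thr)
        sens = cm.tp / n_events
        if sens < min_sensitivity or cm.n_predicted_positive == 0:
            continue
        for i, sc in enumerate(scenarios):
            res = evaluate_scenario(cm, params, sc)
            rows.append(
                {
                    "threshold": float(thr),
                    "sensitivity": sens,
                    "scenario": sc.name or f"Scenario {i + 1}",
                    "net_per_day": res.net_per_day,
                    "cost_per_day": res.cost_per_day,
                }
            )
    frame = pd.DataFrame(
        rows, columns=["threshold", "sensitivity", "scenario", "net_per_day", "cost_per_day"]
    )
    return frame.sort_values(
        ["sensitivity", "scenario"], kind="stable", ignore_index=True
    )
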