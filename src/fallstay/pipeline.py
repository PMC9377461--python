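"""End-to-end pipeline wiring: cohort -> imputation -> matching ->
sensitivity -> classifier evaluation -> decision model.

Each stage writes plain-text artifacts into a run directory and a final
``manifest.json`` records the configuration hash, seeds and stages, so a
rerun with the same configuration reproduces identical outputs. Stages can
also resume from a directory produced by an earlier invocation; a stage
whose upstream artifact is absent fails with a clear message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures
from .classifier_eval import ConfusionMatrix, twofold_threshold_metrics
from .decision_model import Scenario, StayParameters, policy_sweep, scenario_table
from .imputation import ImputationSpec, mice_impute
from .io import read_cohort, read_json, write_cohort, write_json
from .propensity import pooled_matched_analysis
from .sensitivity import sensitivity_table
from .synthetic_cohort import (
    Cohort,
    CohortConfig,
    apply_missingness,
    default_missingness_rates,
    generate_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("fallstay")

ALL_STAGES = (
    "simulate",
    "impute",
    "match",
    "sensitivity",
    "evaluate",
    "decide",
    "sweep",
    "report",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the pipeline in one place.

    ``stages`` selects what runs (in canonical order); the remaining fields
    parameterize the individual stages. Defaults follow the published
    analysis conditions: 20 imputations, a gamma grid up to 8, the four
    published scenarios and stay/cost parameters.
    """

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    n_subjects: int = 20_000
    n_binary_covariates: int = 48
    target_prevalence: float = 0.024
    true_atet: float = 17.8
    score_auc: float = 0.851
    missingness_mechanism: str = "MCAR"
    m_imputations: int = 20
    n_cycles: int = 10
    n_boot: int = 1000
    caliper: float | None = None
    gammas: tuple[float, ...] = fixtures.GAMMA_GRID
    scenarios: tuple[Scenario, ...] = fixtures.SCENARIOS
    stay: StayParameters = field(default_factory=lambda: fixtures.STAY_PARAMETERS)
    min_sensitivity: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "gammas" in data:
            data["gammas"] = tuple(float(g) for g in data["gammas"])
        if "scenarios" in data:
            data["scenarios"] = tuple(
                Scenario(**sc) if isinstance(sc, dict) else sc
                for sc in data["scenarios"]
            )
        if isinstance(data.get("stay"), dict):
            data["stay"] = StayParameters(**data["stay"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        out["gammas"] = list(self.gammas)
        out["scenarios"] = [dataclasses.asdict(sc) for sc in self.scenarios]
        out["stay"] = dataclasses.asdict(self.stay)
        return out

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _cohort_config(config: PipelineConfig) -> CohortConfig:
    return CohortConfig(
        n_subjects=config.n_subjects,
        n_binary_covariates=config.n_binary_covariates,
        target_prevalence=config.target_prevalence,
        true_atet=config.true_atet,
        score_auc=config.score_auc,
        missingness_rates=default_missingness_rates(config.n_binary_covariates),
        seed=config.seed,
    )


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise ValueError(
            f"stage '{needed_by}' needs {path.name} from stage '{stage}'; "
            "run it first or include it in --stages"
        )
    return path


def _load_cohort(outdir: Path, needed_by: str) -> Cohort:
    return read_cohort(_require(outdir / "cohort.csv", "simulate", needed_by))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the configured stages in canonical order; returns the run
    directory. Artifacts are deterministic under a fixed configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config.stages]

    cohort: Cohort | None = None
    imputed: list[Cohort] | None = None
    matched: dict | None = None
    confusion: ConfusionMatrix | None = None

    for stage in stages:
        if stage == "simulate":
            cc = _cohort_config(config)
            cohort = generate_cohort(cc)
            cohort = apply_missingness(
                cohort,
                cc.missingness_rates or {},
                mechanism=config.missingness_mechanism,
                seed=config.seed + 1,
            )
            write_cohort(cohort, outdir / "cohort.csv")
            cfg = dataclasses.asdict(cc)
            cfg["fall_model_coefficients"] = None
            write_json(cfg, outdir / "cohort_config.json")
            logger.info(
                "simulate: n=%d prevalence=%.4f seed=%d",
                cohort.n,
                float(cohort.fall.mean()),
                config.seed,
            )

        elif stage == "impute":
            if cohort is None:
                cohort = _load_cohort(outdir, "impute")
            spec = ImputationSpec(
                m=config.m_imputations, n_cycles=config.n_cycles, seed=config.seed + 2
            )
            imputed = mice_impute(cohort, spec)
            imp_dir = outdir / "imputed"
            imp_dir.mkdir(exist_ok=True)
            names = []
            for i, imp in enumerate(imputed):
                name = f"imputed_{i + 1:02d}.csv"
                write_cohort(imp, imp_dir / name)
                names.append(name)
            write_json(
                {"m": spec.m, "n_cycles": spec.n_cycles, "files": names},
                imp_dir / "manifest.json",
            )
            logger.info("impute: m=%d cycles=%d", spec.m, spec.n_cycles)

        elif stage == "match":
            if cohort is None:
                cohort = _load_cohort(outdir, "match")
            if imputed is None:
                manifest = read_json(
                    _require(outdir / "imputed" / "manifest.json", "impute", "match")
                )
                imputed = [
                    read_cohort(outdir / "imputed" / name) for name in manifest["files"]
                ]
            result = pooled_matched_analysis(
                [imp.covariates for imp in imputed],
                cohort.fall,
                cohort.los,
                n_boot=config.n_boot,
                seed=config.seed + 3,
                caliper=config.caliper,
            )
            matched = result
            est = result["atet"]
            write_json(
                {
                    "point": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_pairs": est.n_pairs,
                },
                outdir / "atet.json",
            )
            result["balance"].to_csv(outdir / "balance.csv", index=False)
            diff_dir = outdir / "pair_diffs"
            diff_dir.mkdir(exist_ok=True)
            for i, pairs in enumerate(result["pairs"]):
                pd.DataFrame({"diff": pairs.pair_diffs(cohort.los)}).to_csv(
                    diff_dir / f"diffs_{i + 1:02d}.csv", index=False
                )
            logger.info(
                "match: atet=%.2f [%.2f, %.2f] pairs=%d",
                est.point,
                est.ci_low,
                est.ci_high,
                est.n_pairs,
            )

        elif stage == "sensitivity":
            if matched is not None and cohort is not None:
                diffs = [p.pair_diffs(cohort.los) for p in matched["pairs"]]
            else:
                diff_dir = _require(outdir / "pair_diffs", "match", "sensitivity")
                diffs = [
                    pd.read_csv(f)["diff"].to_numpy()
                    for f in sorted(diff_dir.glob("diffs_*.csv"))
                ]
                if not diffs:
                    raise ValueError("sensitivity: no pair-difference files found")
            table = sensitivity_table(diffs, config.gammas)
            table.to_csv(outdir / "sensitivity.csv", index=False)
            logger.info("sensitivity: %d gammas", len(config.gammas))

        elif stage == "evaluate":
            if cohort is None:
                cohort = _load_cohort(outdir, "evaluate")
            if cohort.risk_score is None:
                raise ValueError("evaluate: cohort has no risk scores")
            fold = _alternating_folds(cohort.fall)
            metrics, cm = twofold_threshold_metrics(
                cohort.risk_score, cohort.fall, fold
            )
            confusion = cm
            write_json(
                {
                    "auc": metrics.auc,
                    "f1": metrics.f1,
                    "sensitivity": metrics.sensitivity,
                    "specificity": metrics.specificity,
                    "precision": metrics.precision,
                },
                outdir / "metrics.json",
            )
            write_json(
                {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
                outdir / "confusion.json",
            )
            logger.info("evaluate: auc=%.3f cm=(%d,%d,%d,%d)", metrics.auc, cm.tp, cm.fp, cm.fn, cm.tn)

        elif stage == "decide":
            cm = confusion
            if cm is None:
                path = outdir / "confusion.json"
                if path.exists():
                    cm = ConfusionMatrix(**read_json(path))
                else:
                    cm = fixtures.MODEL2_CONFUSION
            table = scenario_table(cm, config.stay, config.scenarios)
            table.to_csv(outdir / "scenario_table.csv", index=False)
            logger.info("decide: %d scenarios on cm=(%d,%d,%d,%d)", len(config.scenarios), cm.tp, cm.fp, cm.fn, cm.tn)

        elif stage == "sweep":
            if cohort is None:
                cohort = _load_cohort(outdir, "sweep")
            if cohort.risk_score is None:
                raise ValueError("sweep: cohort has no risk scores")
            curve = policy_sweep(
                cohort.risk_score,
                cohort.fall,
                config.stay,
                config.scenarios,
                min_sensitivity=config.min_sensitivity,
            )
            curve.to_csv(outdir / "sweep.csv", index=False)
            logger.info("sweep: %d points", len(curve))

        elif stage == "report":
            lines = [f"fallstay run (config {config.config_hash()})"]
            for name in (
                "atet.json",
                "metrics.json",
                "confusion.json",
            ):
                path = outdir / name
                if path.exists():
                    lines.append(f"{name}: {json.dumps(read_json(path), sort_keys=True)}")
            for name in ("sensitivity.csv", "scenario_table.csv"):
                path = outdir / name
                if path.exists():
                    lines.append("")
                    lines.append(f"== {name} ==")
                    lines.append(path.read_text().rstrip())
            (outdir / "report.txt").write_text("\n".join(lines) + "\n")
            logger.info("report: written")

    write_json(
        {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "stages_run": stages,
            "seed": config.seed,
        },
        outdir / "manifest.json",
    )
    return outdir


def _alternating_folds(labels: np.ndarray) -> np.ndarray:
    """Deterministic two-fold split with events (and non-events) balanced
    across folds, mirroring an evaluation-year split with even fall counts."""
    labels = np.asarray(labels)
    fold = np.zeros(labels.shape[0], dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(labels == value)
        fold[idx[1::2]] = 1
    return fold
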