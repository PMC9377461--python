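"""Delimited-text cohort format and small JSON helpers.

A cohort is a UTF-8 comma-separated file with one header row and columns
``id, age_scaled, x01..xK, fall, los, risk_score``; an empty field is a
missing value. ``id``, ``fall`` and ``los`` are required and validated
row by row; covariate missingness round-trips through the mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import Cohort

__all__ = ["read_cohort", "write_cohort", "write_json", "read_json"]


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the observed view of a cohort (masked cells become empty)."""
    path = Path(path)
    frame = cohort.observed()
    out = pd.DataFrame({"id": np.arange(cohort.n, dtype=int)})
    out = pd.concat([out, frame.reset_index(drop=True)], axis=1)
    out["fall"] = cohort.fall.astype(int)
    out["los"] = cohort.los
    out["risk_score"] = cohort.risk_score if cohort.risk_score is not None else np.nan
    out.to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort file, validating ids, fall indicators and stays.

    Validation failures report 1-based data row numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"id", "fall", "los"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {sorted(missing_cols)}")

    ids = frame["id"]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        rows = (dup.index + 1).tolist()
        raise ValueError(f"{path}: duplicate ids at rows {rows}")

    fall = frame["fall"]
    bad = frame.index[~fall.isin([0, 1]) | fall.isna()]
    if len(bad):
        raise ValueError(f"{path}: non-binary fall at rows {(bad + 1).tolist()}")

    los = frame["los"]
    bad = frame.index[los.isna() | (los <= 0)]
    if len(bad):
        raise ValueError(
            f"{path}: missing or non-positive los at rows {(bad + 1).tolist()}"
        )

    cov_cols = [
        c for c in frame.columns if c not in ("id", "fall", "los", "risk_score")
    ]
    covariates = frame[cov_cols].astype(float)
    mask = covariates.isna().to_numpy()
    filled = covariates.fillna(0.0)  # placeholder under the mask

    score = None
    if "risk_score" in frame.columns and not frame["risk_score"].isna().all():
        score = frame["risk_score"].to_numpy(dtype=float)

    return Cohort(
        covariates=filled,
        fall=fall.to_numpy(dtype=np.int8),
        los=los.to_numpy(dtype=float),
        risk_score=score,
        missing_mask=mask,
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
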