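"""Reading/writing cohorts, models, clocks and run metadata.

Cohorts travel as delimited text with a header; models and clocks as
versioned JSON.  Rows with missing values in any mapped column are dropped
(complete-case analysis) with a logged count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bioage import BioAgeClock
from .cohort import Cohort
from .gompertz import GompertzPHModel

__all__ = [
    "ColumnMap",
    "read_cohort",
    "write_cohort",
    "save_clock",
    "load_clock",
    "save_model",
    "load_model",
    "write_run_metadata",
]

logger = logging.getLogger(__name__)

CLOCK_SCHEMA = "goldbioage-clock/1"
MODEL_SCHEMA = "goldbioage-gompertz/1"


@dataclass
class ColumnMap:
    """Mapping from file columns to cohort roles."""

    age: str = "age"
    time: str = "time"
    event: str = "event"
    biomarkers: list[str] = field(default_factory=list)
    subject_id: str | None = None
    sex: str | None = None
    group: str | None = None

    @property
    def required(self) -> list[str]:
        cols = [self.age, self.time, self.event, *self.biomarkers]
        for opt in (self.subject_id, self.sex, self.group):
            if opt is not None:
                cols.append(opt)
        return cols


def read_cohort(path: str | Path, column_map: ColumnMap | None = None, *, sep: str = ",") -> Cohort:
    """Read a delimited cohort table into a typed :class:`Cohort`.

    Rows missing a value in any mapped column are dropped and counted in
    the log.  Unknown biomarker auto-detection: with an empty
    ``column_map.biomarkers`` every numeric column other than the mapped
    roles is treated as a biomarker.
    """
    cm = column_map or ColumnMap()
    df = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in cm.required if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"missing mapped column(s) {missing_cols}; file has {list(df.columns)}"
        )
    if not cm.biomarkers:
        roles = {cm.age, cm.time, cm.event, cm.subject_id, cm.sex, cm.group}
        cm = ColumnMap(
            age=cm.age, time=cm.time, event=cm.event,
            biomarkers=[c for c in df.columns
                        if c not in roles and pd.api.types.is_numeric_dtype(df[c])],
            subject_id=cm.subject_id, sex=cm.sex, group=cm.group,
        )
    mapped = [cm.age, cm.time, cm.event, *cm.biomarkers]
    n0 = len(df)
    df = df.dropna(subset=mapped).reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d row(s) with missing values in mapped columns", dropped)

    for col in (cm.age, cm.time, *cm.biomarkers):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row index "
                f"{int(bad.idxmax())}: {df[col][bad].iloc[0]!r}"
            )
        df[col] = coerced
    ev = pd.to_numeric(df[cm.event], errors="coerce")
    if ev.isna().any() or not ev.isin([0, 1]).all():
        bad_vals = sorted(set(ev.dropna().unique()) - {0, 1})
        raise ValueError(f"event column {cm.event!r} must be 0/1; found {bad_vals}")

    return Cohort(
        age=df[cm.age].to_numpy(float),
        biomarkers=df[cm.biomarkers].astype(float),
        time=df[cm.time].to_numpy(float),
        event=ev.to_numpy(int),
        subject_id=df[cm.subject_id].to_numpy() if cm.subject_id else None,
        sex=df[cm.sex].to_numpy() if cm.sex else None,
        group=df[cm.group].to_numpy() if cm.group else None,
    )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def save_clock(clock: BioAgeClock, path: str | Path) -> None:
    payload = {
        "schema": CLOCK_SCHEMA,
        "provenance": clock.provenance,
        "coefficients": clock.coefficients,
        "constant": clock.constant,
        "reference_values": clock.reference_values,
        "beta1": clock.beta1,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_clock(path: str | Path) -> BioAgeClock:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema", CLOCK_SCHEMA) != CLOCK_SCHEMA:
        raise ValueError(f"unsupported clock schema {payload.get('schema')!r}")
    return BioAgeClock(
        coefficients=payload["coefficients"],
        constant=payload["constant"],
        reference_values=payload.get("reference_values"),
        provenance=payload.get("provenance", "file"),
        beta1=payload.get("beta1"),
    )


def save_model(model: GompertzPHModel, path: str | Path) -> None:
    payload = {
        "schema": MODEL_SCHEMA,
        "rate": model.rate,
        "shape": model.shape,
        "beta_age": model.beta_age,
        "beta_biomarkers": model.beta_biomarkers,
        "loglik": model.loglik,
        "n_subjects": model.n_subjects,
        "n_events": model.n_events,
        "converged": model.converged,
        "grad_max": model.grad_max,
        "message": model.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> GompertzPHModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema", MODEL_SCHEMA) != MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {payload.get('schema')!r}")
    payload.pop("schema", None)
    return GompertzPHModel(**payload)


def write_run_metadata(path: str | Path, *, command: str, seed: int | None, config: dict) -> None:
    """Versioned, hashed record of one CLI run (reproducibility shell)."""
    blob = json.dumps(config, sort_keys=True, default=str)
    payload = {
        "tool": "goldbioage",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
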