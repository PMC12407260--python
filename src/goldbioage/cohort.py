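"""Cohort container: one row per subject, right-censored follow-up.

A :class:`Cohort` bundles chronological age at baseline, a named biomarker
matrix, follow-up time in years and a death indicator, with optional sex and
group labels.  All fitting and evaluation routines in this package consume
this container; reading/writing delimited files lives in :mod:`goldbioage.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Cohort"]


@dataclass
class Cohort:
    """Right-censored survival cohort with baseline biomarkers.

    Parameters
    ----------
    age
        Chronological age at baseline, years.
    biomarkers
        Numeric matrix (subjects x biomarkers) with unique column names.
        May have zero columns.
    time
        Follow-up time in years since baseline, >= 0.
    event
        1 = death observed at ``time``, 0 = censored at ``time``.
    subject_id
        Optional opaque labels, one per subject.
    sex
        Optional categorical sex labels.
    group
        Optional group labels (e.g. study wave, age stratum).
    """

    age: np.ndarray
    biomarkers: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    subject_id: np.ndarray | None = None
    sex: np.ndarray | None = None
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if not isinstance(self.biomarkers, pd.DataFrame):
            self.biomarkers = pd.DataFrame(self.biomarkers)
        n = self.age.shape[0]
        for name, arr in (("time", self.time), ("event", self.event)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
        if len(self.biomarkers) != n:
            raise ValueError(
                f"biomarkers has {len(self.biomarkers)} rows, expected {n}"
            )
        if self.biomarkers.columns.duplicated().any():
            dup = self.biomarkers.columns[self.biomarkers.columns.duplicated()]
            raise ValueError(f"duplicate biomarker columns: {list(dup)}")
        if np.any(self.time < 0):
            raise ValueError("follow-up time must be >= 0")
        ev = np.unique(self.event)
        if not np.isin(ev, [0, 1]).all():
            raise ValueError(f"event must be 0/1, found values {ev}")
        self.event = self.event.astype(int)

    @property
    def n(self) -> int:
        return self.age.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def biomarker_names(self) -> list[str]:
        return [str(c) for c in self.biomarkers.columns]

    def biomarker_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Return the (subjects x len(names)) float matrix in the given order."""
        if names is None:
            names = self.biomarker_names
        missing = [m for m in names if m not in self.biomarkers.columns]
        if missing:
            raise KeyError(f"cohort lacks biomarker column(s): {missing}")
        if not names:
            return np.empty((self.n, 0))
        return self.biomarkers.loc[:, list(names)].to_numpy(dtype=float)

    def subset(self, idx: np.ndarray) -> "Cohort":
        """Row-subset the cohort (boolean mask or integer positions)."""
        take = lambda a: None if a is None else np.asarray(a)[idx]
        return Cohort(
            age=self.age[idx],
            biomarkers=self.biomarkers.iloc[np.arange(self.n)[idx]
                                            if np.asarray(idx).dtype == bool else idx]
            .reset_index(drop=True),
            time=self.time[idx],
            event=self.event[idx],
            subject_id=take(self.subject_id),
            sex=take(self.sex),
            group=take(self.group),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a single DataFrame (age, biomarkers, time, event, ...)."""
        df = pd.DataFrame({"age": self.age})
        df = pd.concat([df, self.biomarkers.reset_index(drop=True)], axis=1)
        df["time"] = self.time
        df["event"] = self.event
        if self.subject_id is not None:
            df.insert(0, "subject_id", self.subject_id)
        if self.sex is not None:
            df["sex"] = self.sex
        if self.group is not None:
            df["group"] = self.group
        return df
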