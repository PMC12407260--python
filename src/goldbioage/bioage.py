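"""Linear biological-age clocks derived from Gompertz hazard models.

Biological age is defined as the chronological age whose model-implied
mortality hazard (age-only model, "model 1") equals the individual's hazard
given age plus biomarkers ("model 2").  Equating the two hazards at t=0 and
solving for age yields a linear clock

    BioAge = CA + sum_i (beta_2i / beta_1) * x_i + constant,

where ``beta_1`` is the age coefficient of model 1 and ``beta_2i`` the
biomarker coefficients of model 2.  The empirical hazards of the two models
differ slightly subject to subject; a bias-correction factor gamma = h1/h2
absorbs that discrepancy into the clock's constant,

    constant = mean_j (1/beta_1) * log( (h1_j / h2_j) * rate_2 / rate_1 ),

with the per-subject hazards evaluated at t=0 over the training cohort.
When model 2 is fitted with its age coefficient constrained to ``beta_1``
this reduces analytically to ``-(1/beta_1) * sum_i beta_2i * mean(x_i)``,
which forces the training-cohort mean of BioAge - CA to zero.

BioAgeDiff = BioAge - CA is the ageing metric: positive values mean ageing
faster than calendar age.  The module also ships the published
three-biomarker "light" clock (creatinine, glucose, log CRP), panel
decomposition of the age gap, and the 0..n_panels count-based risk score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import Cohort
from .gompertz import GompertzPHModel, hazard

__all__ = [
    "BioAgeClock",
    "PanelDefinition",
    "derive_clock",
    "predict_bioage",
    "bioage_diff",
    "light_clock",
    "light_bioage",
    "decompose_diff",
    "risk_score",
]


@dataclass
class BioAgeClock:
    """A linear biological-age clock.

    ``coefficients`` map biomarker name -> years per biomarker unit (the
    beta_2i/beta_1 ratios); ``constant`` is in years and carries the
    gamma bias correction.  ``reference_values`` (optional) are the
    biomarker levels against which the age gap is decomposed; ``beta1``
    records the age coefficient used as denominator (None for published
    clocks whose source models are not available).
    """

    coefficients: dict[str, float]
    constant: float
    reference_values: dict[str, float] | None = None
    provenance: str = "derived"
    beta1: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = {str(k): float(v) for k, v in self.coefficients.items()}
        if not np.isfinite(self.constant):
            raise ValueError("clock constant must be finite")
        if self.reference_values is not None:
            self.reference_values = {
                str(k): float(v) for k, v in self.reference_values.items()
            }

    @property
    def biomarker_names(self) -> list[str]:
        return list(self.coefficients)

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()), dtype=float)


def _clock_x(clock: BioAgeClock, x) -> np.ndarray:
    """Coerce ``x`` to an (n, k) matrix in clock column order."""
    names = clock.biomarker_names
    if isinstance(x, dict):
        missing = [m for m in names if m not in x]
        if missing:
            raise ValueError(f"missing biomarker(s) for clock: {missing}")
        return np.column_stack([np.atleast_1d(np.asarray(x[m], float)) for m in names])
    if isinstance(x, pd.DataFrame):
        missing = [m for m in names if m not in x.columns]
        if missing:
            raise ValueError(f"missing biomarker(s) for clock: {missing}")
        return x.loc[:, names].to_numpy(float)
    xarr = np.atleast_2d(np.asarray(x, dtype=float))
    if xarr.shape[1] != len(names):
        raise ValueError(
            f"x has {xarr.shape[1]} columns, clock expects {len(names)} ({names})"
        )
    return xarr


def derive_clock(
    model1: GompertzPHModel,
    model2: GompertzPHModel,
    cohort: Cohort,
    *,
    gamma: str = "mean-of-logs",
) -> BioAgeClock:
    """Derive the linear clock from an age-only and an age+biomarker fit.

    Parameters
    ----------
    model1
        Age-only Gompertz PH fit (no biomarkers).
    model2
        Age + biomarkers fit on the same subjects; typically fitted with
        its age coefficient constrained to ``model1.beta_age``.
    cohort
        The shared training cohort, used to average the per-subject
        hazard ratio into the constant and to set reference values
        (cohort means).
    gamma
        ``"mean-of-logs"`` (default): constant = mean of
        (1/beta1)*log(h1_j/h2_j * rate2/rate1).
        ``"ratio-of-means"``: a single scalar gamma = mean(h1)/mean(h2)
        plugged into (1/beta1)*log(gamma * rate2/rate1).
    """
    if model1.biomarker_names:
        raise ValueError("model1 must be age-only (no biomarkers)")
    if not model2.biomarker_names:
        raise ValueError("model2 must include at least one biomarker")
    beta1 = model1.beta_age
    if not beta1 > 0:
        raise ValueError(f"clock undefined: model1 age coefficient {beta1} <= 0")
    if gamma not in ("mean-of-logs", "ratio-of-means"):
        raise ValueError(f"unknown gamma estimator {gamma!r}")

    xmat = cohort.biomarker_matrix(model2.biomarker_names)  # raises on mismatch
    h1 = hazard(model1, cohort.age, None, 0.0)
    h2 = hazard(model2, cohort.age, cohort.biomarkers[model2.biomarker_names], 0.0)
    log_rate_ratio = np.log(model2.rate) - np.log(model1.rate)
    if gamma == "mean-of-logs":
        constant = float(np.mean((np.log(h1) - np.log(h2) + log_rate_ratio) / beta1))
    else:
        g = float(np.mean(h1) / np.mean(h2))
        constant = float((np.log(g) + log_rate_ratio) / beta1)

    coefficients = {k: v / beta1 for k, v in model2.beta_biomarkers.items()}
    reference = dict(zip(model2.biomarker_names, xmat.mean(axis=0)))
    return BioAgeClock(
        coefficients=coefficients,
        constant=constant,
        reference_values=reference,
        provenance="derived",
        beta1=beta1,
    )


def predict_bioage(clock: BioAgeClock, age, x) -> np.ndarray | float:
    """BioAge = CA + sum_i coefficient_i * x_i + constant (years)."""
    scalar = np.ndim(age) == 0
    age = np.asarray(age, dtype=float)
    xmat = _clock_x(clock, x)
    out = np.asarray(age + xmat @ clock.coef_vector + clock.constant)
    return float(out.reshape(-1)[0]) if scalar and out.size == 1 else out


def bioage_diff(
    clock: BioAgeClock, age, x, *, return_contributions: bool = False
):
    """BioAge minus chronological age (years).

    With ``return_contributions=True`` (requires ``reference_values``),
    also returns a DataFrame of per-biomarker contributions
    ``coefficient_i * (x_i - ref_i)`` and the residual constant beta0'
    such that contributions.sum(axis=1) + beta0' equals the Diff.
    """
    diff = predict_bioage(clock, age, x) - np.asarray(age, dtype=float)
    if not return_contributions:
        return diff
    if clock.reference_values is None:
        raise ValueError("clock has no reference_values for decomposition")
    xmat = np.atleast_2d(_clock_x(clock, x))
    ref = np.array([clock.reference_values[m] for m in clock.biomarker_names])
    contrib = pd.DataFrame(
        (xmat - ref) * clock.coef_vector, columns=clock.biomarker_names
    )
    beta0_prime = clock.constant + float(ref @ clock.coef_vector)
    return diff, contrib, beta0_prime


def light_clock() -> BioAgeClock:
    """The published three-biomarker clock, loaded from the packaged file.

    Coefficients are in years per unit on the published scales (creatinine,
    glucose, natural-log CRP); no unit conversion is applied.
    """
    payload = json.loads(
        resources.files("goldbioage.data").joinpath("light_clock.json").read_text()
    )
    return BioAgeClock(
        coefficients=payload["coefficients"],
        constant=payload["constant"],
        reference_values=payload.get("reference_values"),
        provenance=payload.get("provenance", "light-published"),
        beta1=payload.get("beta1"),
    )


def light_bioage(age, creatinine, glucose, crp) -> np.ndarray | float:
    """Evaluate the published light clock on raw inputs.

    CRP is natural-log transformed internally and must be > 0.  Units are
    those of the published model; no conversion is attempted.  Negative
    creatinine or glucose is clinically implausible and triggers a warning
    but is still evaluated.
    """
    crp = np.asarray(crp, dtype=float)
    if np.any(crp <= 0):
        raise ValueError("crp must be > 0 (log-transformed internally)")
    creatinine = np.asarray(creatinine, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if np.any(creatinine < 0) or np.any(glucose < 0):
        warnings.warn(
            "negative creatinine/glucose is clinically implausible; "
            "evaluating anyway",
            stacklevel=2,
        )
    return predict_bioage(
        light_clock(),
        age,
        {"creatinine": creatinine, "glucose": glucose, "log_crp": np.log(crp)},
    )


@dataclass
class PanelDefinition:
    """Named partition (or sub-partition) of a clock's biomarkers.

    Each biomarker may appear in at most one panel; biomarkers left out of
    every panel contribute to the total age gap but to no panel.
    """

    panels: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for panel, members in self.panels.items():
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"biomarker {m!r} assigned to both {seen[m]!r} and {panel!r}"
                    )
                seen[m] = panel

    @property
    def assigned(self) -> list[str]:
        return [m for members in self.panels.values() for m in members]


def decompose_diff(
    clock: BioAgeClock, panels: PanelDefinition, cohort: Cohort
) -> pd.DataFrame:
    """Split each subject's age gap into per-panel contributions.

    Panel p's Diff is ``sum_{i in p} coefficient_i * (x_i - mean_i)`` with
    cohort-mean centering, so every panel Diff has mean zero over the
    cohort and the panel Diffs (plus unassigned-biomarker terms) sum to
    the centered total Diff.
    """
    unknown = [m for m in panels.assigned if m not in clock.coefficients]
    if unknown:
        raise ValueError(f"panel biomarker(s) not in clock: {unknown}")
    xmat = cohort.biomarker_matrix(clock.biomarker_names)
    centered = (xmat - xmat.mean(axis=0)) * clock.coef_vector
    contrib = pd.DataFrame(centered, columns=clock.biomarker_names)
    out = {}
    for panel, members in panels.panels.items():
        out[panel] = contrib[members].sum(axis=1) if members else 0.0
    return pd.DataFrame(out)


def risk_score(panel_diffs: pd.DataFrame, quantile: float = 0.25) -> np.ndarray:
    """Count of panels in which a subject is in the top ``quantile``.

    A subject scores one point per panel whose Diff is at or above the
    empirical (1 - quantile) threshold — values tied with the threshold
    count as high-risk — giving an integer in 0..n_panels.
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    if panel_diffs.shape[1] < 1:
        raise ValueError("need at least one panel")
    thresholds = panel_diffs.quantile(1.0 - quantile, axis=0)
    return (panel_diffs.ge(thresholds, axis=1)).sum(axis=1).to_numpy()
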