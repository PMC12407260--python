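"""Benchmarking battery for ageing clocks on right-censored cohorts.

Discrimination (Harrell's C-index), fixed-horizon mortality AUC via a
single-variable logistic model, Kaplan-Meier stratification by age-gap
quantile, Cox hazard ratios per year of age gap, and the two linear
comparator metrics (PCA age, Mahalanobis distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .cohort import Cohort

__all__ = [
    "c_index",
    "horizon_auc",
    "HorizonAUC",
    "km_quantile_groups",
    "cox_hr_per_year",
    "CoxHRResult",
    "pca_age",
    "mahalanobis_mds",
    "EvaluationReport",
    "evaluate_clock_scores",
]


def c_index(score, time, event) -> float:
    """Harrell's concordance index of a risk score.

    A pair is comparable when the earlier observed time is an event;
    concordant when the earlier-dying subject has the higher score; ties
    in score count 0.5.
    """
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not (score.shape == time.shape == event.shape):
        raise ValueError("score, time, event must have equal length")
    # lifelines treats higher prediction = longer survival; negate the risk
    return float(concordance_index(time, -score, event))


@dataclass
class HorizonAUC:
    """AUC for death within a fixed horizon. ``auc_model`` is computed from
    fitted logistic probabilities, ``auc_rank`` directly from the score
    ranks (they coincide up to logistic monotonicity)."""

    auc_model: float
    auc_rank: float
    horizon: float
    n_used: int
    n_excluded: int


def horizon_auc(score, time, event, horizon: float = 10.0) -> HorizonAUC:
    """AUC for predicting death within ``horizon`` years from a single score.

    Outcome 1 = died by the horizon; 0 = followed past the horizon alive.
    Subjects censored before the horizon without an event carry no usable
    label and are excluded (simple-exclusion convention).
    """
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    died = (event == 1) & (time <= horizon)
    alive = time > horizon
    usable = died | alive
    y = died[usable].astype(int)
    s = score[usable]
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(
            f"degenerate outcome at horizon {horizon}: "
            f"{int(y.sum())} deaths among {y.size} usable subjects"
        )
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(s.reshape(-1, 1), y)
    prob = lr.predict_proba(s.reshape(-1, 1))[:, 1]
    return HorizonAUC(
        auc_model=float(roc_auc_score(y, prob)),
        auc_rank=float(roc_auc_score(y, s)),
        horizon=float(horizon),
        n_used=int(y.size),
        n_excluded=int((~usable).sum()),
    )


def km_quantile_groups(
    diff,
    time,
    event,
    quantile: float = 0.25,
    *,
    age=None,
    age_bins: tuple[tuple[float, float], ...] = ((45, 54), (55, 64), (65, 74), (75, 85)),
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier curves for the top- and bottom-quantile age-gap groups.

    Returns a mapping group-label -> survival table (time, survival,
    Greenwood log-log 95% band, n).  With ``age`` given, groups are formed
    within each age stratum; thresholds use the closed-upper-set tie rule
    (>= upper threshold is high risk, <= lower threshold low risk).
    """
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    diff = np.asarray(diff, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    def strata():
        if age is None:
            yield "", np.ones(diff.shape[0], bool)
        else:
            a = np.asarray(age, float)
            for lo, hi in age_bins:
                yield f"age{lo:g}-{hi:g}/", (a >= lo) & (a <= hi)

    out: dict[str, pd.DataFrame] = {}
    for prefix, mask in strata():
        d = diff[mask]
        if d.size == 0:
            raise ValueError(f"empty stratum {prefix!r}")
        hi_thr = np.quantile(d, 1 - quantile)
        lo_thr = np.quantile(d, quantile)
        for label, sel in (("high", d >= hi_thr), ("low", d <= lo_thr)):
            idx = np.flatnonzero(mask)[sel]
            if idx.size == 0:
                raise ValueError(f"empty group {prefix}{label}")
            kmf = KaplanMeierFitter()
            kmf.fit(time[idx], event[idx], alpha=0.05)
            ci = kmf.confidence_interval_survival_function_
            out[prefix + label] = pd.DataFrame(
                {
                    "time": kmf.survival_function_.index.to_numpy(),
                    "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                    "lower95": ci.iloc[:, 0].to_numpy(),
                    "upper95": ci.iloc[:, 1].to_numpy(),
                }
            ).assign(n=idx.size)
    return out


@dataclass
class CoxHRResult:
    """Hazard ratio per +1 unit of the score with Wald 95% CI."""

    hr: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    adjusted_for: list[str] = field(default_factory=list)


def cox_hr_per_year(
    diff, time, event, *, age=None, sex=None
) -> CoxHRResult:
    """Cox PH hazard ratio per +1 year of age gap (Breslow ties).

    Optionally adjusted for chronological age and sex, mirroring standard
    mortality-association models.
    """
    df = pd.DataFrame(
        {"diff": np.asarray(diff, float), "time": np.asarray(time, float),
         "event": np.asarray(event, int)}
    )
    adjusted = []
    if age is not None:
        df["age"] = np.asarray(age, float)
        adjusted.append("age")
    if sex is not None:
        sex = np.asarray(sex)
        codes, _ = pd.factorize(sex)
        df["sex"] = codes
        adjusted.append("sex")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["diff"])
    se = float(cph.standard_errors_["diff"])
    z = 1.959963984540054
    return CoxHRResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        beta=beta,
        se=se,
        adjusted_for=adjusted,
    )


def pca_age(cohort: Cohort, n_components: int = 5) -> np.ndarray:
    """PCA-based comparator age: first principal components regressed on age.

    Biomarkers are standardized, the first ``n_components`` principal
    component scores are extracted, and chronological age is regressed on
    them by least squares; the fitted value is each subject's PCA age.
    """
    X = cohort.biomarker_matrix()
    if X.shape[1] == 0:
        raise ValueError("cohort has no biomarkers")
    if X.shape[1] < n_components:
        warnings.warn(
            f"only {X.shape[1]} biomarkers available; using all of them "
            f"instead of {n_components} components",
            stacklevel=2,
        )
        n_components = X.shape[1]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(Z)
    design = np.column_stack([np.ones(len(scores)), scores])
    coef, *_ = np.linalg.lstsq(design, cohort.age, rcond=None)
    return design @ coef


def mahalanobis_mds(
    cohort: Cohort,
    *,
    mean: np.ndarray | None = None,
    cov: np.ndarray | None = None,
    reference_mask: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Mahalanobis distance of each subject's biomarker vector.

    The reference mean/covariance default to the cohort itself, or to the
    ``reference_mask`` subsample (e.g. young adults).  A singular
    covariance is ridge-regularized with a warning.
    """
    X = cohort.biomarker_matrix()
    ref = X if reference_mask is None else X[np.asarray(reference_mask, bool)]
    mu = ref.mean(axis=0) if mean is None else np.asarray(mean, float)
    sigma = np.cov(ref, rowvar=False, ddof=1) if cov is None else np.asarray(cov, float)
    sigma = np.atleast_2d(sigma)
    ev = np.linalg.eigvalsh(sigma)
    if ev[0] <= 1e-10 * max(ev[-1], 1.0):
        warnings.warn(
            "singular reference covariance; applying ridge regularization",
            stacklevel=2,
        )
        sigma = sigma + ridge * np.eye(sigma.shape[0]) * max(1.0, np.trace(sigma))
    chol = np.linalg.cholesky(sigma)
    w = solve_triangular(chol, (X - mu).T, lower=True)
    return np.sqrt(np.sum(w**2, axis=0))


@dataclass
class EvaluationReport:
    """Benchmark results for one clock score on one cohort."""

    clock_name: str
    c_index: float
    auc: HorizonAUC | None
    hr: CoxHRResult | None
    km: dict[str, pd.DataFrame] | None
    group_rule: str = "top/bottom 25% of age gap"

    def summary(self) -> dict:
        out = {"clock": self.clock_name, "c_index": self.c_index}
        if self.auc is not None:
            out["auc_horizon"] = self.auc.horizon
            out["auc"] = self.auc.auc_model
        if self.hr is not None:
            out["hr_per_year"] = self.hr.hr
            out["hr_ci"] = [self.hr.ci_low, self.hr.ci_high]
        return out


def evaluate_clock_scores(
    scores: dict[str, np.ndarray],
    cohort: Cohort,
    *,
    horizon: float = 10.0,
    quantile: float = 0.25,
    adjust_age: bool = True,
) -> list[EvaluationReport]:
    """Run the full battery for each named score on one cohort."""
    reports = []
    for name, score in scores.items():
        diff = np.asarray(score, float)
        try:
            auc = horizon_auc(diff, cohort.time, cohort.event, horizon)
        except ValueError:
            auc = None
        hr = cox_hr_per_year(
            diff,
            cohort.time,
            cohort.event,
            age=cohort.age if adjust_age else None,
            sex=cohort.sex,
        )
        km = km_quantile_groups(diff, cohort.time, cohort.event, quantile)
        reports.append(
            EvaluationReport(
                clock_name=name,
                c_index=c_index(diff, cohort.time, cohort.event),
                auc=auc,
                hr=hr,
                km=km,
            )
        )
    return reports
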