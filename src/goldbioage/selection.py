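"""L1-penalized Cox feature selection with cross-validated penalty choice.

Candidate biomarkers are standardized internally (so the selected support
does not depend on measurement units), an elastic-net Cox path with pure
L1 penalty is fitted, and the penalty is chosen by k-fold cross-validated
Harrell C-index — either the maximizing penalty, the parsimonious
one-standard-deviation rule, or an externally fixed value.  Subsampling
stability frequencies quantify how robustly each biomarker is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .cohort import Cohort

__all__ = ["SelectionResult", "lasso_cox_select", "stability_subsample"]


@dataclass
class SelectionResult:
    """Outcome of one penalized-selection run.

    ``lambda_path`` is decreasing; ``cv_cindex_mean``/``sd`` align with it.
    ``coefficients`` are the nonzero refit coefficients at
    ``chosen_lambda``, mapped back to the candidates' native units.
    """

    lambda_path: np.ndarray
    cv_cindex_mean: np.ndarray
    cv_cindex_sd: np.ndarray
    chosen_lambda: float
    selected: list[str]
    coefficients: dict[str, float]
    stability: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "lambda_path": [float(v) for v in self.lambda_path],
            "cv_cindex_mean": [float(v) for v in self.cv_cindex_mean],
            "cv_cindex_sd": [float(v) for v in self.cv_cindex_sd],
            "chosen_lambda": float(self.chosen_lambda),
            "selected": list(self.selected),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "stability": self.stability,
        }


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _coxnet_coefs(Z, y, lam: float) -> np.ndarray:
    """Pure-L1 coxnet coefficients at a single penalty."""
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lam], fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, y)
    return model.coef_[:, 0]


def lasso_cox_select(
    cohort: Cohort,
    candidate_biomarkers: list[str],
    *,
    k_folds: int = 5,
    lambda_rule: str | float = "max_cindex",
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
) -> SelectionResult:
    """Select biomarkers by L1-penalized Cox regression with k-fold CV.

    Parameters
    ----------
    cohort
        Survival cohort; needs at least ``k_folds`` events.
    candidate_biomarkers
        Numeric columns to screen.
    lambda_rule
        ``"max_cindex"``: penalty maximizing the mean CV C-index.
        ``"one_sd"``: largest penalty whose mean CV C-index is within one
        standard deviation of the maximum (parsimony rule).
        A float: that penalty, used exactly.
    seed
        Drives the (event-stratified, shuffled) fold assignment.
    """
    X = cohort.biomarker_matrix(list(candidate_biomarkers))
    names = list(candidate_biomarkers)
    if cohort.n_events < k_folds:
        raise ValueError(
            f"need >= {k_folds} events for {k_folds}-fold CV, "
            f"have {cohort.n_events}"
        )
    Z, _, sd = _standardize(X)
    y = Surv.from_arrays(event=cohort.event.astype(bool), time=cohort.time)

    path_model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        n_alphas=n_lambdas,
        alpha_min_ratio=lambda_min_ratio,
        fit_baseline_model=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path_model.fit(Z, y)
    lambda_path = np.asarray(path_model.alphas_, dtype=float)

    folds = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    cv = np.full((k_folds, lambda_path.size), np.nan)
    for f, (tr, te) in enumerate(folds.split(Z, cohort.event)):
        fold_model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=lambda_path, fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_model.fit(Z[tr], y[tr])
        for a, lam in enumerate(lambda_path):
            pred = fold_model.predict(Z[te], alpha=lam)
            if np.ptp(pred) == 0:
                cv[f, a] = 0.5  # null model: no discrimination
            else:
                cv[f, a] = concordance_index_censored(
                    cohort.event[te].astype(bool), cohort.time[te], pred
                )[0]
    mean = cv.mean(axis=0)
    sd_cv = cv.std(axis=0, ddof=1)

    if isinstance(lambda_rule, (int, float)):
        chosen = float(lambda_rule)
    elif lambda_rule == "max_cindex":
        chosen = float(lambda_path[int(np.argmax(mean))])
    elif lambda_rule == "one_sd":
        best = int(np.argmax(mean))
        ok = mean >= mean[best] - sd_cv[best]
        chosen = float(lambda_path[np.flatnonzero(ok)[0]])  # path is decreasing
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    coef_std = _coxnet_coefs(Z, y, chosen)
    support = np.flatnonzero(coef_std != 0)
    if support.size == 0:
        warnings.warn(
            f"empty support at lambda={chosen:g}; returning no biomarkers",
            stacklevel=2,
        )
    coefficients = {
        names[i]: float(coef_std[i] / sd[i]) for i in support
    }
    return SelectionResult(
        lambda_path=lambda_path,
        cv_cindex_mean=mean,
        cv_cindex_sd=sd_cv,
        chosen_lambda=chosen,
        selected=[names[i] for i in support],
        coefficients=coefficients,
    )


def stability_subsample(
    cohort: Cohort,
    candidate_biomarkers: list[str],
    *,
    n_reps: int = 50,
    frac: float = 0.8,
    seed: int = 0,
    penalty: float | None = None,
    k_folds: int = 5,
) -> dict[str, float]:
    """Per-biomarker selection frequency over subsamples without replacement.

    Each replicate refits the pure-L1 Cox model on a ``frac`` subsample at
    a single penalty (chosen once on the full cohort by cross-validated
    C-index unless ``penalty`` is given) and records the nonzero support.
    Deterministic given ``seed``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    names = list(candidate_biomarkers)
    if penalty is None:
        penalty = lasso_cox_select(
            cohort, names, k_folds=k_folds, seed=seed
        ).chosen_lambda

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(names))
    m = max(2, int(round(frac * cohort.n)))
    for _ in range(n_reps):
        while True:
            idx = rng.choice(cohort.n, size=m, replace=False)
            if cohort.event[idx].sum() >= 2:
                break
        sub = cohort.subset(np.sort(idx))
        Z, _, _ = _standardize(sub.biomarker_matrix(names))
        y = Surv.from_arrays(event=sub.event.astype(bool), time=sub.time)
        coef = _coxnet_coefs(Z, y, penalty)
        counts += coef != 0
    return {n: float(c / n_reps) for n, c in zip(names, counts)}
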