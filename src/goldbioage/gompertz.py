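"""Gompertz proportional-hazards mortality models.

The hazard of death at time ``t`` (years since baseline) for a subject with
chronological age ``CA`` and biomarker vector ``x`` is modelled as

    h(t) = rate * exp(beta_age * CA + sum_i beta_i * x_i + shape * t)

i.e. a Gompertz baseline ``rate * exp(shape * t)`` multiplied by a
proportional-hazards term in baseline age and biomarkers.  The module
provides the hazard and cumulative-hazard functions, the right-censored
log-likelihood, and maximum-likelihood fitting in a free variant and a
variant with the age coefficient constrained to a given value (the protocol
used to derive interpretable biological-age clocks, see
:mod:`goldbioage.bioage`).

Fitting is parameterized over ``log(rate)`` so positivity is structural;
the shape may be negative (declining hazard) — nothing forbids it.
Biomarkers enter on their native scale so downstream clock coefficients
keep their clinical units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .cohort import Cohort

__all__ = [
    "GompertzPHModel",
    "hazard",
    "cumulative_hazard",
    "log_likelihood",
    "fit",
]

logger = logging.getLogger(__name__)

# series cut-over for (e^u - 1)/u and its derivative; below this the direct
# expression loses precision to cancellation
_SMALL_U = 1e-5


def _phi1(u: np.ndarray) -> np.ndarray:
    """(e^u - 1)/u, continuous at u=0 where it equals 1."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < _SMALL_U
    us = u[small]
    out[small] = 1.0 + us / 2.0 + us**2 / 6.0 + us**3 / 24.0
    ub = u[~small]
    out[~small] = np.expm1(ub) / ub
    return out


def _phi1_prime(u: np.ndarray) -> np.ndarray:
    """d/du [(e^u - 1)/u] = (e^u (u - 1) + 1)/u^2, -> 1/2 at u=0."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < _SMALL_U
    us = u[small]
    out[small] = 0.5 + us / 3.0 + us**2 / 8.0 + us**3 / 30.0
    ub = u[~small]
    out[~small] = (np.exp(ub) * (ub - 1.0) + 1.0) / ub**2
    return out


def _cumhaz_time_factor(shape: float, t: np.ndarray) -> np.ndarray:
    """Integral of exp(shape*s) ds over [0, t]: t * phi1(shape*t)."""
    t = np.asarray(t, dtype=float)
    return t * _phi1(shape * t)


@dataclass
class GompertzPHModel:
    """A fitted (or hypothesised) Gompertz proportional-hazards model.

    Attributes
    ----------
    rate
        Baseline hazard scale at ``t=0`` and zero linear predictor
        (per year, > 0).
    shape
        Gompertz time coefficient (per year of follow-up); may be negative.
    beta_age
        Coefficient of chronological age (per year of age).
    beta_biomarkers
        Ordered mapping biomarker name -> coefficient (per biomarker unit).
        Empty for an age-only ("model 1") specification.
    loglik
        Log-likelihood at the stored parameters (NaN if never evaluated).
    n_subjects, n_events
        Fit metadata.
    converged
        True when the optimizer met both the relative log-likelihood and
        gradient criteria.
    grad_max
        Max-norm of the per-subject-scaled score at the stored parameters.
    message
        Optimizer diagnostics.
    """

    rate: float
    shape: float
    beta_age: float = 0.0
    beta_biomarkers: dict[str, float] = field(default_factory=dict)
    loglik: float = float("nan")
    n_subjects: int = 0
    n_events: int = 0
    converged: bool = True
    grad_max: float = float("nan")
    message: str = ""

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        self.beta_biomarkers = dict(self.beta_biomarkers)

    @property
    def biomarker_names(self) -> list[str]:
        return list(self.beta_biomarkers)

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array(list(self.beta_biomarkers.values()), dtype=float)

    def linear_predictor(self, age, x=None) -> np.ndarray:
        """beta_age * age + sum_i beta_i * x_i (excludes the shape*t term)."""
        age = np.asarray(age, dtype=float)
        lp = self.beta_age * age
        xmat = _coerce_x(self, x, n=age.shape[0] if age.ndim else None)
        if xmat.shape[1]:
            lp = lp + xmat @ self.beta_vector
        return lp


def _coerce_x(model: GompertzPHModel, x, n: int | None = None) -> np.ndarray:
    """Validate and shape a biomarker vector/matrix/dict against the model.

    Returns a 2-D float array with columns in ``model.biomarker_names``
    order (possibly zero columns).  Raises on missing or extra biomarkers.
    """
    names = model.biomarker_names
    k = len(names)
    if x is None:
        if k:
            raise ValueError(f"missing biomarkers: model requires {names}, got none")
        return np.empty((n or 1, 0))
    if isinstance(x, dict):
        missing = [m for m in names if m not in x]
        extra = [m for m in x if m not in names]
        if missing or extra:
            raise ValueError(
                f"biomarker mismatch: missing {missing}, unexpected {extra}"
            )
        cols = [np.asarray(x[m], dtype=float) for m in names]
        xmat = np.column_stack([np.atleast_1d(c) for c in cols]) if k else np.empty((n or 1, 0))
        return xmat
    # pandas objects carry names worth validating
    cols_attr = getattr(x, "columns", None)
    if cols_attr is not None:
        return _coerce_x(model, {str(c): x[c] for c in cols_attr}, n=n)
    xarr = np.atleast_2d(np.asarray(x, dtype=float))
    if k == 0 and xarr.size == 0:
        return np.empty((n or 1, 0))
    if xarr.shape[1] != k:
        raise ValueError(
            f"x has {xarr.shape[1]} biomarker column(s), model expects "
            f"{k} ({names})"
        )
    return xarr


def hazard(model: GompertzPHModel, age, x=None, t=0.0) -> np.ndarray | float:
    """Mortality hazard rate * exp(beta_age*age + sum beta_i*x_i + shape*t).

    ``age``, ``t`` and the rows of ``x`` broadcast; ``t`` must be >= 0.
    Strictly positive by construction.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    scalar = np.ndim(age) == 0 and t.ndim == 0
    lp = model.linear_predictor(age, x)
    out = np.asarray(model.rate * np.exp(lp + model.shape * t))
    return float(out.reshape(-1)[0]) if scalar and out.size == 1 else out


def cumulative_hazard(model: GompertzPHModel, age, x=None, t=0.0):
    """Integrated hazard H(t) = rate * e^lp * (e^{shape t} - 1)/shape.

    Continuous in shape at 0, where it reduces to the exponential
    ``rate * e^lp * t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    scalar = np.ndim(age) == 0 and t.ndim == 0
    lp = model.linear_predictor(age, x)
    out = np.asarray(model.rate * np.exp(lp) * _cumhaz_time_factor(model.shape, t))
    return float(out.reshape(-1)[0]) if scalar and out.size == 1 else out


def survival(model: GompertzPHModel, age, x=None, t=0.0):
    """S(t) = exp(-H(t))."""
    return np.exp(-cumulative_hazard(model, age, x, t))


def log_likelihood(model: GompertzPHModel, cohort: Cohort) -> float:
    """Right-censored log-likelihood of the cohort under the model.

    sum over subjects of ``event_i * log h(t_i) - H(t_i)``.
    """
    if not model.rate > 0:
        raise ValueError("rate must be > 0")
    xmat = cohort.biomarker_matrix(model.biomarker_names)
    for name, arr in (
        ("age", cohort.age),
        ("time", cohort.time),
        ("biomarkers", xmat),
    ):
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite values in cohort {name}")
    lp = model.beta_age * cohort.age
    if xmat.shape[1]:
        lp = lp + xmat @ model.beta_vector
    log_h = np.log(model.rate) + lp + model.shape * cohort.time
    cum_h = model.rate * np.exp(lp) * _cumhaz_time_factor(model.shape, cohort.time)
    return float(np.sum(cohort.event * log_h) - np.sum(cum_h))


def _neg_loglik_and_grad(
    theta: np.ndarray,
    age: np.ndarray,
    xmat: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    free_shape: bool,
    free_age: bool,
    fixed_shape: float,
    fixed_beta_age: float,
) -> tuple[float, np.ndarray]:
    """Per-subject-averaged negative log-likelihood and gradient.

    theta = [log_rate, (shape), (beta_age), beta_biomarkers...]
    """
    n = age.shape[0]
    i = 0
    log_rate = theta[i]; i += 1
    shape = theta[i] if free_shape else fixed_shape
    i += free_shape
    beta_age = theta[i] if free_age else fixed_beta_age
    i += free_age
    betas = theta[i:]

    lp = beta_age * age
    if xmat.shape[1]:
        lp = lp + xmat @ betas
    u = shape * time
    g = time * _phi1(u)                       # (e^{st}-1)/s
    H = np.exp(log_rate + lp) * g             # cumulative hazard
    D = event.sum()
    ll = (
        event @ (log_rate + lp + u)
        - H.sum()
    )

    grad = np.empty_like(theta)
    j = 0
    grad[j] = D - H.sum(); j += 1             # d/d log_rate
    if free_shape:
        gs = time**2 * _phi1_prime(u)         # d/ds of the time factor
        grad[j] = event @ time - np.exp(log_rate + lp) @ gs
        j += 1
    resid = event - H                         # common score weight
    if free_age:
        grad[j] = resid @ age; j += 1
    if xmat.shape[1]:
        grad[j:] = resid @ xmat
    return -ll / n, -grad / n


def fit(
    cohort: Cohort,
    biomarker_names: list[str] | tuple[str, ...] = (),
    *,
    include_age: bool = True,
    fixed_beta_age: float | None = None,
    fixed_shape: float | None = None,
    init: dict | None = None,
) -> GompertzPHModel:
    """Maximum-likelihood Gompertz PH fit on a right-censored cohort.

    Parameters
    ----------
    cohort
        The training cohort; needs >= 2 events and finite values in every
        fitted column.
    biomarker_names
        Biomarker columns to include (empty for an age-only model).
    include_age
        Include chronological age in the linear predictor.  Set False for
        a pure baseline (used e.g. to recover an exponential rate).
    fixed_beta_age
        Constrain the age coefficient to this exact value instead of
        estimating it (the shared-age-coefficient clock protocol).  The
        remaining parameters — rate, shape and biomarker coefficients —
        are re-estimated under the constraint.
    fixed_shape
        Fix the Gompertz time coefficient (e.g. 0 for an exponential model)
        instead of estimating it.
    init
        Optional overrides for the starting point: keys among
        ``shape``, ``beta_age``, ``log_rate`` and ``beta_biomarkers``
        (a name -> value mapping).

    Returns
    -------
    GompertzPHModel
        With ``converged=False`` plus diagnostics in ``message`` (rather
        than an exception) if the optimizer stalls.
    """
    names = [str(b) for b in biomarker_names]
    xmat = cohort.biomarker_matrix(names)
    age = cohort.age
    time = cohort.time
    event = cohort.event

    if event.sum() == 0:
        raise ValueError("no events in cohort: Gompertz MLE undefined")
    if event.sum() < 2:
        raise ValueError("need >= 2 events to fit")
    for label, arr in (("age", age), ("time", time), ("biomarkers", xmat)):
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite values in fitted column(s): {label}")

    if xmat.shape[1] >= 2:
        sv = np.linalg.svd(xmat - xmat.mean(axis=0), compute_uv=False)
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        if cond > 1e10:
            warnings.warn(
                f"biomarker matrix is near rank-deficient (condition number "
                f"{cond:.3g}); fit proceeds but coefficients may be unstable",
                stacklevel=2,
            )
            logger.warning("biomarker condition number %.3g", cond)

    free_shape = fixed_shape is None
    free_age = include_age and fixed_beta_age is None
    beta_age0 = (
        (fixed_beta_age if fixed_beta_age is not None else 0.08)
        if include_age
        else 0.0
    )
    shape0 = 0.08 if free_shape else float(fixed_shape)
    init = init or {}
    if free_shape:
        shape0 = float(init.get("shape", shape0))
    if free_age:
        beta_age0 = float(init.get("beta_age", beta_age0))

    # conditional MLE of the rate at the starting betas: D / sum(e^lp * g)
    lp0 = beta_age0 * age
    g0 = time * _phi1(shape0 * time)
    denom = float(np.exp(lp0) @ g0)
    log_rate0 = float(init.get("log_rate", np.log(event.sum() / denom)))

    theta0 = [log_rate0]
    if free_shape:
        theta0.append(shape0)
    if free_age:
        theta0.append(beta_age0)
    beta0 = init.get("beta_biomarkers", {})
    theta0.extend([float(beta0.get(b, 0.0)) for b in names])
    theta0 = np.array(theta0, dtype=float)

    args = (
        age,
        xmat,
        time,
        event,
        free_shape,
        free_age,
        float(fixed_shape or 0.0),
        float(beta_age0 if not free_age else 0.0),
    )
    res = minimize(
        _neg_loglik_and_grad,
        theta0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-9},
    )
    # polish: a second pass from the optimum tightens the scaled score
    res2 = minimize(
        _neg_loglik_and_grad,
        res.x,
        args=args,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-11},
    )
    if res2.fun <= res.fun:
        res = res2

    f, grad = _neg_loglik_and_grad(res.x, *args)
    grad_max = float(np.max(np.abs(grad)))
    n = cohort.n
    converged = bool(grad_max <= 1e-4)

    i = 0
    log_rate = res.x[i]; i += 1
    shape = float(res.x[i]) if free_shape else float(fixed_shape)
    i += free_shape
    beta_age = float(res.x[i]) if free_age else (beta_age0 if include_age else 0.0)
    i += free_age
    betas = dict(zip(names, (float(b) for b in res.x[i:])))

    model = GompertzPHModel(
        rate=float(np.exp(log_rate)),
        shape=shape,
        beta_age=beta_age,
        beta_biomarkers=betas,
        loglik=float(-f * n),
        n_subjects=n,
        n_events=int(event.sum()),
        converged=converged,
        grad_max=grad_max,
        message=str(res.message),
    )
    if not converged:
        logger.warning(
            "Gompertz fit did not meet the gradient criterion "
            "(max |score|/n = %.3g): %s",
            grad_max,
            res.message,
        )
    return model
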