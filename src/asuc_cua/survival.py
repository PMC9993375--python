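"""Parametric time-to-colectomy models and transition-probability schedules.

The long-term model needs the per-cycle probability that a patient still in
medically-maintained remission undergoes colectomy.  That probability is
extrapolated from two-year censored trial follow-up by fitting a
proportional-hazards Weibull regression

    h(t | x) = lambda * gamma * t**(gamma - 1) * exp(x' beta)
    S(t | x) = exp(-lambda * t**gamma * exp(x' beta))

so reported hazard ratios are exp(beta).  gamma < 1 gives the declining
colectomy hazard seen after the acute phase.  Alternative families
(exponential, Gompertz in PH form, log-logistic in AFT form) are fitted for
comparison by AIC/BIC only.

A fitted (gamma, lambda) pair is converted into an annual-cycle schedule of
time-dependent transition probabilities via the survival-ratio construction

    tp(t) = 1 - S(t)/S(t-1) = 1 - exp(-lambda e^{x'beta} (t**gamma - (t-1)**gamma))

and period probabilities are interconverted with constant rates by
r = -ln(1 - P)/T, p = 1 - exp(-r T).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, ValidationError

FAMILIES = ("weibull", "exponential", "gompertz", "loglogistic")

_TIME_COL = "observed_time_years"
_EVENT_COL = "event"


# ---------------------------------------------------------------------------
# log-likelihood machinery
#
# theta layout per family (betas appended after the family parameters):
#   weibull:     [log gamma, log lambda]
#   exponential: [log lambda]
#   gompertz:    [gamma, log lambda]          (gamma may be negative)
#   loglogistic: [log gamma, log alpha]       (AFT: alpha_i = alpha e^{x'b})
# ---------------------------------------------------------------------------


def _n_family_params(family: str) -> int:
    return 1 if family == "exponential" else 2


def _log_hazard_cumhaz(family, theta, t, logt, X):
    """Return (log h_i, H_i) arrays at parameter vector ``theta``."""
    p = _n_family_params(family)
    beta = theta[p:]
    lp = X @ beta if X.size else np.zeros_like(t)
    if family == "weibull":
        gamma = math.exp(theta[0])
        log_lambda = theta[1]
        log_h = log_lambda + theta[0] + (gamma - 1.0) * logt + lp
        H = np.exp(log_lambda + lp) * t**gamma
    elif family == "exponential":
        log_lambda = theta[0]
        log_h = log_lambda + lp
        H = np.exp(log_lambda + lp) * t
    elif family == "gompertz":
        gamma = theta[0]
        log_lambda = theta[1]
        log_h = log_lambda + gamma * t + lp
        if abs(gamma) < 1e-10:
            grow = t
        else:
            grow = np.expm1(gamma * t) / gamma
        H = np.exp(log_lambda + lp) * grow
    elif family == "loglogistic":
        gamma = math.exp(theta[0])
        log_alpha_i = theta[1] + lp  # acceleration acts on the time scale
        z = gamma * (logt - log_alpha_i)
        log1pz = np.logaddexp(0.0, z)
        log_h = theta[0] - logt + z - log1pz
        H = log1pz  # -log S
    else:  # pragma: no cover - guarded by caller
        raise ValidationError(f"unknown family {family!r}")
    return log_h, H


def _neg_loglik(theta, family, t, logt, d, X):
    log_h, H = _log_hazard_cumhaz(family, theta, t, logt, X)
    ll = np.sum(d * log_h) - np.sum(H)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _numerical_hessian(f, x, eps=1e-5):
    x = np.asarray(x, dtype=float)
    k = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


@dataclass
class SurvivalModelFit:
    """Maximum-likelihood fit of a parametric right-censored survival model.

    ``shape``/``scale`` are (gamma, lambda) for the hazard-based families and
    (shape, location-scale alpha) for the log-logistic AFT.  ``coefficients``
    are covariate log hazard ratios (PH families) or log time ratios
    (log-logistic).  ``covariate_center`` records the profile at which the
    baseline scale applies; linear predictors are evaluated relative to it.
    """

    family: str
    shape: float
    scale: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    aic: float
    bic: float
    n: int
    n_events: int
    converged: bool = True
    covariate_center: dict[str, float] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return _n_family_params(self.family) + len(self.coefficients)

    def hazard_ratios(self) -> dict[str, float]:
        return {name: math.exp(b) for name, b in self.coefficients.items()}

    def linear_predictor(self, profile: Mapping[str, float] | None = None) -> float:
        """x'beta at ``profile``, relative to the fitted centering profile.

        ``profile=None`` evaluates at the centering profile itself (lp = 0).
        """
        if profile is None:
            return 0.0
        lp = 0.0
        for name, b in self.coefficients.items():
            lp += b * (profile[name] - self.covariate_center.get(name, 0.0))
        return lp

    def cumulative_hazard(self, t, profile=None) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        elp = math.exp(self.linear_predictor(profile))
        if self.family == "weibull":
            return self.scale * t**self.shape * elp
        if self.family == "exponential":
            return self.scale * t * elp
        if self.family == "gompertz":
            g = self.shape
            grow = t if abs(g) < 1e-10 else np.expm1(g * t) / g
            return self.scale * grow * elp
        if self.family == "loglogistic":
            # acceleration: alpha_i = alpha * exp(lp)
            z = (t / (self.scale * elp)) ** self.shape
            return np.log1p(z)
        raise ValidationError(f"unknown family {self.family!r}")

    def survival(self, t, profile=None) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(t, profile))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "shape": self.shape,
            "scale": self.scale,
            "coefficients": dict(self.coefficients),
            "standard_errors": dict(self.standard_errors),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "n_events": self.n_events,
            "converged": bool(self.converged),
            "covariate_center": dict(self.covariate_center),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def loglik_at(fit: SurvivalModelFit, records: pd.DataFrame) -> float:
    """Evaluate the right-censored log-likelihood of ``records`` at a fit.

    Direct evaluation of sum(d log h) - sum(H); used to confirm that the
    reported optimum log-likelihood is the likelihood at the reported
    parameters.
    """
    t, logt, d, X, _ = _design(records, tuple(fit.coefficients), fit.covariate_center)
    theta = _pack_theta(fit.family, fit.shape, fit.scale, list(fit.coefficients.values()))
    return -_neg_loglik(theta, fit.family, t, logt, d, X)


def _pack_theta(family, shape, scale, betas):
    if family == "exponential":
        head = [math.log(scale)]
    elif family == "gompertz":
        head = [shape, math.log(scale)]
    else:
        head = [math.log(shape), math.log(scale)]
    return np.asarray(head + list(betas), dtype=float)


def _design(records, covariate_names, center):
    t = records[_TIME_COL].to_numpy(dtype=float)
    d = records[_EVENT_COL].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValidationError("observed times must be > 0")
    if covariate_names:
        raw = records[list(covariate_names)].to_numpy(dtype=float)
        if center is None:
            center = {c: float(m) for c, m in zip(covariate_names, raw.mean(axis=0))}
        X = raw - np.array([center[c] for c in covariate_names])
    else:
        X = np.empty((len(t), 0))
        center = {}
    return t, np.log(t), d, X, center


def fit_parametric(
    records: pd.DataFrame,
    family: str = "weibull",
    covariate_names: Sequence[str] = (),
    center: Mapping[str, float] | None = None,
) -> SurvivalModelFit:
    """Fit a parametric survival model to right-censored records by ML.

    ``records`` needs columns ``observed_time_years`` and ``event`` (1 =
    colectomy, 0 = censored) plus any ``covariate_names``.  Covariates are
    centred at ``center`` (default: their sample means), so the fitted scale
    is the baseline at that profile.  Standard errors come from the inverse
    observed information (delta method back to the natural scale for
    log-parameterised shape/scale).
    """
    if family not in FAMILIES:
        raise ValidationError(f"family must be one of {FAMILIES}; got {family!r}")
    covariate_names = tuple(covariate_names)
    t, logt, d, X, center = _design(records, covariate_names, dict(center) if center else None)
    n = len(t)
    n_events = int(d.sum())
    if n_events < 1 or (n_events < 2 and _n_family_params(family) + len(covariate_names) > 1):
        raise FitError(f"need at least 2 events to fit {family}; got {n_events}")

    # exponential with no covariates has the closed-form MLE lambda = d / sum(t)
    rate0 = n_events / t.sum()
    if family == "exponential" and not covariate_names:
        theta = np.array([math.log(rate0)])
        converged = True
    else:
        from scipy.optimize import minimize

        if family == "exponential":
            x0 = [math.log(rate0)]
        elif family == "gompertz":
            x0 = [0.0, math.log(rate0)]
        elif family == "loglogistic":
            x0 = [0.0, -math.log(rate0)]
        else:
            x0 = [0.0, math.log(rate0)]
        x0 = np.asarray(x0 + [0.0] * len(covariate_names))
        args = (family, t, logt, d, X)
        res = minimize(_neg_loglik, x0, args=args, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        res = minimize(_neg_loglik, res.x, args=args, method="BFGS",
                       options={"gtol": 1e-9, "maxiter": 500})
        if not np.isfinite(res.fun):
            raise FitError(f"{family} fit diverged: {res.message}")
        theta = res.x
        converged = bool(res.success) or np.linalg.norm(res.jac) < 1e-4 * max(1.0, abs(res.fun))
        if not converged:
            raise FitError(
                f"{family} fit did not converge: {res.message}; |grad|={np.linalg.norm(res.jac):.3g}"
            )

    ll = -_neg_loglik(theta, family, t, logt, d, X)
    k = theta.size
    aic = 2 * k - 2 * ll
    bic = k * math.log(n) - 2 * ll

    H = _numerical_hessian(lambda th: _neg_loglik(th, family, t, logt, d, X), theta)
    try:
        cov = np.linalg.inv(H)
        se_theta = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_theta = np.full(k, np.nan)

    p = _n_family_params(family)
    if family == "exponential":
        shape, scale = 1.0, math.exp(theta[0])
        se = {"scale": scale * se_theta[0]}
    elif family == "gompertz":
        shape, scale = theta[0], math.exp(theta[1])
        se = {"shape": se_theta[0], "scale": scale * se_theta[1]}
    else:
        shape, scale = math.exp(theta[0]), math.exp(theta[1])
        se = {"shape": shape * se_theta[0], "scale": scale * se_theta[1]}
    betas = {name: float(b) for name, b in zip(covariate_names, theta[p:])}
    se.update({name: float(s) for name, s in zip(covariate_names, se_theta[p:])})

    return SurvivalModelFit(
        family=family,
        shape=float(shape),
        scale=float(scale),
        coefficients=betas,
        standard_errors=se,
        log_likelihood=float(ll),
        aic=float(aic),
        bic=float(bic),
        n=n,
        n_events=n_events,
        converged=converged,
        covariate_center=center,
    )


def compare_fits(fits: Sequence[SurvivalModelFit]) -> pd.DataFrame:
    """Rank fits of the same data by AIC and BIC.

    Ties are broken by fewer parameters, then family name.  Fits on
    differing record/event counts cannot be compared.
    """
    if not fits:
        raise ValidationError("no fits to compare")
    key = (fits[0].n, fits[0].n_events)
    for f in fits[1:]:
        if (f.n, f.n_events) != key:
            raise ValidationError(
                f"fits are not on identical data: (n, events) {key} vs {(f.n, f.n_events)}"
            )
    rows = [
        {
            "family": f.family,
            "k": f.n_params,
            "log_likelihood": f.log_likelihood,
            "aic": f.aic,
            "bic": f.bic,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    for crit in ("aic", "bic"):
        order = df.sort_values([crit, "k", "family"]).index
        df.loc[order, f"rank_{crit}"] = np.arange(1, len(df) + 1)
        df[f"rank_{crit}"] = df[f"rank_{crit}"].astype(int)
    return df.sort_values("rank_aic").reset_index(drop=True)


# ---------------------------------------------------------------------------
# transition-probability schedules
# ---------------------------------------------------------------------------


@dataclass
class TPSchedule:
    """Per-cycle colectomy transition probabilities for the cohort model."""

    probabilities: np.ndarray  # tp(1..H)
    cycle_length: float = 1.0  # years
    source: str = "weibull_time_dependent"  # or "fixed"

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValidationError("transition probabilities must lie in [0, 1]")

    def __len__(self):
        return len(self.probabilities)

    def tp(self, cycle: int) -> float:
        """Probability for model year ``cycle`` (1-based)."""
        return float(self.probabilities[cycle - 1])

    def cumulative_event_probability(self) -> float:
        return float(1.0 - np.prod(1.0 - self.probabilities))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"cycle": np.arange(1, len(self) + 1), "probability": self.probabilities}
        ).to_csv(path, index=False)


def weibull_tp_schedule(
    shape: float, scale: float, horizon_cycles: int, linear_predictor: float = 0.0,
    cycle_length: float = 1.0,
) -> TPSchedule:
    """Annual colectomy probabilities from Weibull (gamma, lambda) directly.

    tp(t) = 1 - exp(-lambda e^{lp} (t**gamma - (t-1)**gamma)) in cycle units.
    Strictly decreasing in t when gamma < 1, constant when gamma = 1.
    """
    if horizon_cycles < 1:
        raise ValidationError(f"horizon_cycles must be >= 1; got {horizon_cycles}")
    if not shape > 0 or not scale > 0:
        raise ValidationError("weibull shape and scale must be > 0")
    tt = np.arange(1, horizon_cycles + 1, dtype=float) * cycle_length
    prev = tt - cycle_length
    probs = 1.0 - np.exp(-scale * math.exp(linear_predictor) * (tt**shape - prev**shape))
    return TPSchedule(probs, cycle_length=cycle_length, source="weibull_time_dependent")


def tp_schedule_from_weibull(
    fit: SurvivalModelFit,
    covariate_profile: Mapping[str, float] | None = None,
    horizon_cycles: int = 18,
) -> TPSchedule:
    """Annual-cycle transition probabilities from a fitted Weibull model.

    ``covariate_profile`` fixes the covariates (default: the fit's centering
    profile, i.e. the covariate means used at fit time).
    """
    if fit.family != "weibull":
        raise ValidationError(f"need a weibull fit; got family {fit.family!r}")
    lp = fit.linear_predictor(covariate_profile)
    return weibull_tp_schedule(fit.shape, fit.scale, horizon_cycles, linear_predictor=lp)


def fixed_tp_schedule(probability: float, horizon_cycles: int) -> TPSchedule:
    """A constant per-cycle colectomy probability (fixed-TP scenario)."""
    if not 0.0 <= probability <= 1.0:
        raise ValidationError(f"fixed tp must lie in [0, 1]; got {probability}")
    if horizon_cycles < 1:
        raise ValidationError(f"horizon_cycles must be >= 1; got {horizon_cycles}")
    return TPSchedule(np.full(horizon_cycles, probability), source="fixed")


# ---------------------------------------------------------------------------
# rate <-> probability conversions
# ---------------------------------------------------------------------------


def rate_from_probability(p: float, period_years: float) -> float:
    """Constant annual event rate implied by probability ``p`` over a period.

    r = -ln(1 - p) / T.  Used e.g. to turn a published 3-year mortality
    probability into the yearly rate the annual-cycle model needs.
    """
    if not 0.0 <= p < 1.0:
        if p == 1.0:
            raise ValidationError("probability 1 implies an infinite rate")
        raise ValidationError(f"probability must lie in [0, 1); got {p}")
    if period_years <= 0:
        raise ValidationError(f"period must be > 0; got {period_years}")
    return -math.log1p(-p) / period_years


def probability_from_rate(rate: float, period_years: float = 1.0) -> float:
    """Event probability over ``period_years`` under constant annual ``rate``."""
    if rate < 0:
        raise ValidationError(f"rate must be >= 0; got {rate}")
    if period_years <= 0:
        raise ValidationError(f"period must be > 0; got {period_years}")
    return -math.expm1(-rate * period_years)


def annualise_probability(p: float, period_years: float) -> float:
    """Convert a probability over ``period_years`` into a 1-year probability."""
    return probability_from_rate(rate_from_probability(p, period_years), 1.0)


# ---------------------------------------------------------------------------
# non-parametric checks
# ---------------------------------------------------------------------------


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier colectomy-free survival (product-limit estimate)."""
    from lifelines import KaplanMeierFitter

    if records[_EVENT_COL].sum() < 1:
        raise ValidationError("need at least one event for a KM estimate")
    kmf = KaplanMeierFitter()
    kmf.fit(records[_TIME_COL], records[_EVENT_COL])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(records: pd.DataFrame, arm_col: str = "arm") -> tuple[float, float]:
    """Two-arm log-rank test; returns (chi-square statistic, p-value)."""
    from lifelines.statistics import logrank_test as _lr

    arms = records[arm_col].unique()
    if len(arms) != 2:
        raise ValidationError(f"log-rank test needs exactly 2 arms; got {list(arms)}")
    a = records[records[arm_col] == arms[0]]
    b = records[records[arm_col] == arms[1]]
    res = _lr(
        a[_TIME_COL], b[_TIME_COL], event_observed_A=a[_EVENT_COL], event_observed_B=b[_EVENT_COL]
    )
    return float(res.test_statistic), float(res.p_value)
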