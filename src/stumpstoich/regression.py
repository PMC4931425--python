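"""Linear vs. exponential regression of wood chemistry on ergosterol.

For each response (an element concentration, or a C:x / N:x ratio) two model
forms are fitted against ergosterol concentration x:

    linear       y = a + b·x                 (ordinary least squares)
    exponential  y = a·exp(b·x)              (nonlinear least squares on the
                                              original scale, initialized from
                                              OLS of ln y on x)

Forms are compared with the least-squares AIC, n·ln(RSS/n) + 2q with q = 3
parameters (a, b, error variance) for both forms, so additive constants
cancel; the smaller AIC wins, ties going to the simpler linear form.
Significance is a two-sided t-test on the slope for the linear form and an
F-test against the intercept-only model for the exponential form; p-values
are Bonferroni-corrected within each response family.

Because concentration noise in this system is multiplicative (variance grows
with the mean), the slope confidence intervals attached to each fit are
heteroscedasticity-robust: an HC3 sandwich interval for the linear form and
the exact log-scale OLS interval for the exponential form (under lognormal
multiplicative noise the log-model is Gaussian).  p-values are left on the
classic original-scale definitions above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .core import ELEMENTS, StumpSample
from .errors import (AlignmentError, ConvergenceError, DegenerateDesignError,
                     ElementDivisionError)

_N_PARAMS = 3  # a, b, error variance — identical for both forms
_RSS_FLOOR = 1e-300


@dataclass(frozen=True)
class RegressionFit:
    """One fitted model for one response."""

    response_label: str
    model_form: str            # "linear" | "exponential"
    a: float                   # intercept (linear) / scale (exponential)
    b: float                   # slope (linear) / rate (exponential)
    r2: float
    aic: float
    p_value: float
    p_adjusted: float
    n: int
    b_se: float
    b_ci95: tuple[float, float]


def _aic(rss: float, n: int) -> float:
    return n * math.log(max(rss, _RSS_FLOOR) / n) + 2 * _N_PARAMS


def _as_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError(
            f"x and y must be equal-length 1-d vectors, got {x.shape} "
            f"and {y.shape}")
    if x.size < 3:
        raise DegenerateDesignError(f"need n >= 3 points, got {x.size}")
    return x, y


def fit_linear(x, y, response_label: str = "y") -> RegressionFit:
    """OLS fit y = a + b·x with r², least-squares AIC and slope t-test."""
    x, y = _as_arrays(x, y)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("fit_linear: x is constant")
    n = x.size
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    # HC3 sandwich interval for the slope (robust to variance ∝ mean²).
    robust = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC3")
    lo, hi = robust.conf_int()[1]
    return RegressionFit(response_label, "linear",
                         float(res.intercept), float(res.slope),
                         r2, _aic(rss, n), p, p,
                         n, float(robust.bse[1]), (float(lo), float(hi)))


def fit_exponential(x, y, response_label: str = "y",
                    maxfev: int = 10_000) -> RegressionFit:
    """Nonlinear least-squares fit y = a·exp(b·x) on the original scale.

    Initialized from OLS of ln y on x (hence y must be strictly positive).
    r² and AIC are computed on the original scale, comparably with
    :func:`fit_linear`; p comes from an F-test of the fitted model against
    the intercept-only model with (1, n−2) degrees of freedom.
    """
    x, y = _as_arrays(x, y)
    if np.any(y <= 0):
        raise ElementDivisionError(
            "fit_exponential: y must be strictly positive for log "
            "initialization")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("fit_exponential: x is constant")
    n = x.size
    log_init = stats.linregress(x, np.log(y))
    p0 = (math.exp(log_init.intercept), log_init.slope)

    def model(xv, a, b):
        return a * np.exp(np.clip(b * xv, -700, 700))

    init_fit = _exponential_fit_from_params(
        x, y, p0[0], p0[1], response_label, log_init)
    try:
        with warnings.catch_warnings():
            # singular parameter covariance is expected on noiseless input
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            params, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=maxfev)
    except RuntimeError as err:
        raise ConvergenceError(
            f"fit_exponential({response_label}): {err}", init_fit=init_fit
        ) from None
    a_hat, b_hat = float(params[0]), float(params[1])
    return _exponential_fit_from_params(x, y, a_hat, b_hat,
                                        response_label, log_init)


def _exponential_fit_from_params(x, y, a_hat, b_hat, response_label,
                                 log_init) -> RegressionFit:
    n = x.size
    fitted = a_hat * np.exp(np.clip(b_hat * x, -700, 700))
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if rss <= 0 or tss <= rss:
        f_stat = math.inf if tss > rss else 0.0
    else:
        f_stat = ((tss - rss) / 1.0) / (rss / (n - 2))
    p = float(stats.f.sf(f_stat, 1, n - 2)) if math.isfinite(f_stat) else 0.0
    # Exact log-scale OLS interval for the rate parameter.
    t_crit = stats.t.ppf(0.975, n - 2)
    se = float(log_init.stderr)
    ci = (log_init.slope - t_crit * se, log_init.slope + t_crit * se)
    return RegressionFit(response_label, "exponential", a_hat, b_hat,
                         r2, _aic(rss, n), p, p, n, se,
                         (float(ci[0]), float(ci[1])))


def select_model(linear: RegressionFit,
                 exponential: RegressionFit,
                 tie_tol: float = 1e-9) -> RegressionFit:
    """Return the fit with the smaller AIC; ties go to the linear form."""
    if linear.response_label != exponential.response_label:
        raise AlignmentError(
            f"select_model: responses differ ({linear.response_label!r} vs "
            f"{exponential.response_label!r})")
    if linear.n != exponential.n:
        raise AlignmentError("select_model: sample sizes differ")
    if abs(linear.aic - exponential.aic) < tie_tol:
        return linear
    return linear if linear.aic < exponential.aic else exponential


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: each p mapped to min(1, m·p), order preserved."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than the number of "
                         f"p-values ({len(p_values)})")
    out = []
    for p in p_values:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p!r} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


RESPONSE_FAMILIES = ("concentration", "C_ratio", "N_ratio")


def family_responses(response_family: str) -> list[str]:
    """Response labels making up one family (and its Bonferroni size)."""
    if response_family == "concentration":
        return list(ELEMENTS)
    if response_family == "C_ratio":
        return [f"C:{e}" for e in ELEMENTS if e != "C"]
    if response_family == "N_ratio":
        return [f"N:{e}" for e in ELEMENTS if e not in ("C", "N")]
    raise ValueError(
        f"unknown response family {response_family!r}; expected one of "
        f"{RESPONSE_FAMILIES}")


def _response_vector(samples: Sequence[StumpSample], label: str) -> np.ndarray:
    if ":" in label:
        num, den = label.split(":")
        return np.array([s.profile[num] / s.profile[den] for s in samples])
    return np.array([s.profile[label] for s in samples])


def run_suite(samples: Sequence[StumpSample],
              response_family: str = "concentration") -> list[RegressionFit]:
    """Fit both forms per response, select by AIC, Bonferroni-correct.

    x is the stumps' ergosterol concentration; the family size m equals the
    number of responses in the family (12 concentrations, 11 C:x ratios or
    10 N:x ratios).  Results are sorted by r² descending.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise DegenerateDesignError(
            f"run_suite: need at least 3 stumps, got {len(samples)}")
    labels = family_responses(response_family)
    x = np.array([s.ergosterol_ug_g for s in samples])
    selected = []
    for label in labels:
        y = _response_vector(samples, label)
        lin = fit_linear(x, y, label)
        try:
            exp = fit_exponential(x, y, label)
        except ConvergenceError as err:
            exp = err.init_fit
        selected.append(select_model(lin, exp))
    adjusted = bonferroni([f.p_value for f in selected], m=len(labels))
    selected = [replace(f, p_adjusted=p_adj)
                for f, p_adj in zip(selected, adjusted)]
    selected.sort(key=lambda f: f.r2, reverse=True)
    return selected


def fits_to_frame(fits: Sequence[RegressionFit]):
    """Tabular layout used by the CSV outputs."""
    import pandas as pd

    return pd.DataFrame(
        [{"response": f.response_label, "model_form": f.model_form,
          "a": f.a, "b": f.b, "r2": f.r2, "aic": f.aic,
          "p": f.p_value, "p_adj": f.p_adjusted, "n": f.n}
         for f in fits])
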