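"""Maximum-likelihood inference for the NBPF-Weibull distribution.

The log-likelihood for observations ``w_1..w_n`` is, with
``t_i = delta*w_i - alpha/w_i``, ``A_i = exp(t_i)`` and
``G_i = 1 - exp(-A_i)``:

    l(alpha, delta, beta) = sum log(delta + alpha/w_i^2) + sum t_i - sum A_i
                            - n log(beta) + sum log(B_i)

where the bracket ``B_i`` depends on the density mode:

    consistent:  B_i = 1 + log(beta) * beta**G_i   (true CDF derivative)
    as_printed:  B_i = 1 + log(beta) * G_i         (variant bracket)

The analytic score (gradient in (alpha, delta, beta)) is supplied to a
bounded quasi-Newton optimizer (L-BFGS-B).  Fitting proceeds by nesting:
the two-parameter F-Weibull sub-model (beta = 1) is fitted first from a
moment heuristic, then the full model is started from the sub-model fit
with several initial values of beta; the best local maximum is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .distributions import NBPFParams, PDF_MODES, _check_mode
from .errors import DataValidationError, DomainError
from . import distributions as dist

__all__ = [
    "Sample",
    "FitResult",
    "OptimizerOptions",
    "ProfileCurve",
    "log_likelihood",
    "score",
    "fit_mle",
    "profile_loglik",
]

_PENALTY = 1e10  # finite stand-in for -inf log-likelihood inside line searches


@dataclass(frozen=True)
class Sample:
    """An ordered collection of strictly positive, finite event times."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).ravel()
        if arr.size < 1:
            raise DataValidationError("sample must contain at least one observation")
        bad = ~np.isfinite(arr) | (arr <= 0.0)
        if np.any(bad):
            rows = np.flatnonzero(bad)
            raise DataValidationError(
                f"observations must be positive finite reals; offending rows: {rows.tolist()}"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class OptimizerOptions:
    """Settings for the bounded quasi-Newton fit.

    ``lower``/``upper`` bound alpha and delta; ``beta_lower`` bounds the
    transform parameter separately at exp(-1), the smallest value for which
    the density bracket 1 + log(beta)*beta**G stays nonnegative over the
    whole support (below it the model is not a distribution and the
    pseudo-likelihood is unbounded as beta -> 0).  ``beta_starts`` are the
    initial values of beta tried from the fitted sub-model.
    """

    lower: float = 1e-8
    upper: float = 1e3
    beta_lower: float = float(np.exp(-1))
    tol: float = 1e-8
    maxiter: int = 500
    beta_starts: tuple[float, ...] = (0.5, 1.0, 2.0)
    mode: str = "consistent"


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    estimates: object
    loglik_max: float
    converged: bool
    n_obs: int
    mode: str
    restarts_used: int = 0
    optimizer_message: str = ""
    model: str = "nbpf-weibull"

    def params_dict(self) -> dict:
        est = self.estimates
        if isinstance(est, dict):
            return dict(est)
        return {k: getattr(est, k) for k in ("alpha", "delta", "beta", "gamma") if hasattr(est, k)}


@dataclass(frozen=True)
class ProfileCurve:
    """Profile log-likelihood of one parameter (others re-maximized per point)."""

    parameter_name: str
    grid: np.ndarray
    profile_loglik: np.ndarray
    loglik_max: float


def _as_values(sample: Union[Sample, Sequence[float], np.ndarray]) -> np.ndarray:
    if isinstance(sample, Sample):
        return sample.values
    return Sample(np.asarray(sample, dtype=float)).values


def _pieces(w: np.ndarray, alpha: float, delta: float):
    t = np.clip(delta * w - alpha / w, -dist._T_MAX, dist._T_MAX)
    a = np.exp(t)
    e_neg_a = np.exp(-a)
    g = -np.expm1(-a)
    return t, a, e_neg_a, g


def _loglik_terms(w: np.ndarray, theta: np.ndarray, mode: str):
    """Return (loglik, grad) for parameter vector theta = (alpha, delta, beta).

    Returns (-_PENALTY, zeros) when the bracket B_i is nonpositive somewhere
    (possible in either mode for beta < exp(-1)), so optimizers backtrack
    instead of propagating NaNs.
    """
    alpha, delta, beta = theta
    t, a, e_neg_a, g = _pieces(w, alpha, delta)
    d = delta + alpha / w**2
    lb = np.log(beta)
    if mode == "consistent":
        p = np.exp(g * lb)  # beta**G
        bracket = 1.0 + lb * p
        dbracket_dg = lb * lb * p
        dbracket_dbeta = p * (1.0 + g * lb) / beta
    else:
        bracket = 1.0 + lb * g
        dbracket_dg = np.full_like(g, lb)
        dbracket_dbeta = g / beta
    if np.any(bracket <= 0.0) or np.any(d <= 0.0):
        return -_PENALTY, np.zeros(3)
    n = w.size
    ll = float(np.sum(np.log(d)) + np.sum(t) - np.sum(a) - n * lb + np.sum(np.log(bracket)))
    # dG/dalpha = -A e^{-A} / w ; dG/ddelta = w A e^{-A}
    ae = a * e_neg_a
    ratio = dbracket_dg / bracket
    d_alpha = float(
        np.sum(1.0 / (w**2 * d)) - np.sum(1.0 / w) + np.sum(a / w) - np.sum(ratio * ae / w)
    )
    d_delta = float(np.sum(1.0 / d) + np.sum(w) - np.sum(w * a) + np.sum(ratio * ae * w))
    d_beta = float(-n / beta + np.sum(dbracket_dbeta / bracket))
    return ll, np.array([d_alpha, d_delta, d_beta])


def log_likelihood(
    sample: Union[Sample, Sequence[float]],
    p: NBPFParams,
    mode: str = "consistent",
) -> float:
    """Log-likelihood of the sample under ``p`` (equals sum of log densities)."""
    _check_mode(mode)
    w = _as_values(sample)
    ll, _ = _loglik_terms(w, np.array([p.alpha, p.delta, p.beta]), mode)
    return ll


def score(
    sample: Union[Sample, Sequence[float]],
    p: NBPFParams,
    mode: str = "consistent",
) -> np.ndarray:
    """Analytic gradient of the log-likelihood in (alpha, delta, beta)."""
    _check_mode(mode)
    w = _as_values(sample)
    _, grad = _loglik_terms(w, np.array([p.alpha, p.delta, p.beta]), mode)
    return grad


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _fw_nll(theta: np.ndarray, w: np.ndarray):
    """Negative log-likelihood and gradient of the F-Weibull sub-model."""
    alpha, delta = theta
    t, a, _, _ = _pieces(w, alpha, delta)
    d = delta + alpha / w**2
    if np.any(d <= 0.0):
        return _PENALTY, np.zeros(2)
    ll = np.sum(np.log(d)) + np.sum(t) - np.sum(a)
    d_alpha = np.sum(1.0 / (w**2 * d)) - np.sum(1.0 / w) + np.sum(a / w)
    d_delta = np.sum(1.0 / d) + np.sum(w) - np.sum(w * a)
    return -ll, -np.array([d_alpha, d_delta])


# The optimizer works on x = log(theta): positivity is automatic, the very
# different natural scales of alpha and delta are equalized, and line
# searches stay in numerically sane territory on this surface's flat ridges.


def _fw_nll_log(x: np.ndarray, w: np.ndarray):
    theta = np.exp(x)
    nll, grad = _fw_nll(theta, w)
    with np.errstate(over="ignore", invalid="ignore"):
        g = np.nan_to_num(grad * theta, nan=0.0, posinf=1e12, neginf=-1e12)
    return min(nll, _PENALTY), g


def fit_fweibull(
    sample: Union[Sample, Sequence[float]],
    options: Optional[OptimizerOptions] = None,
) -> FitResult:
    """Fit the two-parameter F-Weibull sub-model (beta fixed at 1)."""
    opts = options or OptimizerOptions()
    w = _as_values(sample)
    # moment heuristic: delta0 = 1/mean, alpha0 = mean
    mean = float(np.mean(w))
    start = np.log(np.array([mean, 1.0 / mean]))
    bounds = [(np.log(opts.lower), np.log(opts.upper))] * 2
    res = minimize(
        _fw_nll_log,
        np.clip(start, np.log(opts.lower), np.log(opts.upper)),
        args=(w,),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": opts.maxiter, "ftol": opts.tol, "gtol": 1e-8},
    )
    alpha, delta = np.exp(res.x)
    return FitResult(
        estimates=NBPFParams(max(alpha, opts.lower), max(delta, opts.lower), 1.0),
        loglik_max=-float(res.fun),
        converged=bool(res.success),
        n_obs=w.size,
        mode=opts.mode,
        optimizer_message=str(res.message),
        model="f-weibull",
    )


def _nll_full(theta: np.ndarray, w: np.ndarray, mode: str):
    ll, grad = _loglik_terms(w, theta, mode)
    return -ll, -grad


def _nll_full_log(x: np.ndarray, w: np.ndarray, mode: str):
    theta = np.exp(x)
    nll, grad = _nll_full(theta, w, mode)
    with np.errstate(over="ignore", invalid="ignore"):
        g = np.nan_to_num(grad * theta, nan=0.0, posinf=1e12, neginf=-1e12)
    return min(nll, _PENALTY), g


def fit_mle(
    sample: Union[Sample, Sequence[float]],
    mode: str = "consistent",
    options: Optional[OptimizerOptions] = None,
    extra_starts: Sequence[Sequence[float]] = (),
) -> FitResult:
    """Fit the three-parameter NBPF-Weibull by multi-start bounded L-BFGS-B.

    The F-Weibull sub-model is fitted first; the full model is then started
    from its estimates with each value in ``options.beta_starts`` (plus any
    ``extra_starts`` triples).  The best finite local maximum is returned;
    by the nesting argument its log-likelihood is never below the
    sub-model's.  Failures never raise — ``converged=False`` with the
    optimizer's message is returned instead.
    """
    _check_mode(mode)
    opts = options or OptimizerOptions()
    opts = replace(opts, mode=mode)
    w = _as_values(sample)
    sub = fit_fweibull(w, opts)
    sub_params = sub.estimates
    starts = [
        np.array([sub_params.alpha, sub_params.delta, b0]) for b0 in opts.beta_starts
    ]
    for s in extra_starts:
        starts.append(np.asarray(s, dtype=float))
    lowers = np.array([opts.lower, opts.lower, opts.beta_lower])
    log_lo = np.log(lowers)
    log_hi = np.full(3, np.log(opts.upper))
    bounds = list(zip(log_lo, log_hi))
    best = None
    n_tried = 0
    messages = []
    for start in starts:
        x0 = np.clip(np.log(np.clip(start, lowers, opts.upper)), log_lo, log_hi)
        try:
            res = minimize(
                _nll_full_log,
                x0,
                args=(w, mode),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": opts.maxiter, "ftol": opts.tol, "gtol": 1e-8},
            )
        except (FloatingPointError, OverflowError) as exc:  # pragma: no cover
            messages.append(str(exc))
            continue
        n_tried += 1
        messages.append(str(res.message))
        if not np.isfinite(res.fun) or res.fun >= _PENALTY / 2:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is not None:
        # derivative-free polish: the ridge in (alpha, beta) is nearly flat
        # (the CDF has zero first-order sensitivity to beta at beta=1), where
        # quasi-Newton line searches stall short of the optimum
        polish = minimize(
            lambda x: _nll_full_log(np.clip(x, log_lo, log_hi), w, mode)[0],
            best.x,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if np.isfinite(polish.fun) and polish.fun < best.fun:
            best = polish
            best.x = np.clip(polish.x, log_lo, log_hi)
    if best is None:
        return FitResult(
            estimates=NBPFParams(1.0, 1.0, 1.0),
            loglik_max=-np.inf,
            converged=False,
            n_obs=w.size,
            mode=mode,
            restarts_used=n_tried,
            optimizer_message="; ".join(messages) or "all starts failed",
        )
    theta = np.exp(np.clip(best.x, log_lo, log_hi))
    alpha, delta, beta = np.maximum(theta, lowers)
    params = NBPFParams(alpha, delta, beta)
    loglik = -float(best.fun)
    at_bound = bool(np.any(np.isclose(theta, lowers, rtol=1e-6)) or np.any(np.isclose(theta, opts.upper, rtol=1e-6)))
    # judge convergence by the first-order condition itself, not the
    # optimizer's flag: line searches can report failure at a point whose
    # (scale-free, log-space) gradient is already negligible
    _, grad = _loglik_terms(w, theta, mode)
    score_ok = bool(np.max(np.abs(grad * theta)) < 1e-3)
    converged = np.isfinite(loglik) and not at_bound and (bool(best.success) or score_ok)
    # prefer the sub-model when the extra parameter buys nothing; beta = 1 is
    # an interior stationary point (the beta-score vanishes identically there)
    if sub.converged and sub.loglik_max > loglik:
        params = sub.estimates
        loglik = sub.loglik_max
        converged = True
    return FitResult(
        estimates=params,
        loglik_max=loglik,
        converged=converged,
        n_obs=w.size,
        mode=mode,
        restarts_used=n_tried,
        optimizer_message=str(best.message),
    )


_PARAM_INDEX = {"alpha": 0, "delta": 1, "beta": 2}


def profile_loglik(
    sample: Union[Sample, Sequence[float]],
    parameter_name: str,
    grid: Optional[Sequence[float]] = None,
    mode: str = "consistent",
    options: Optional[OptimizerOptions] = None,
) -> ProfileCurve:
    """Profile log-likelihood curve for one parameter.

    At each grid value the held parameter is fixed and the other two are
    re-maximized (warm-started at the full MLE).  The default grid spans
    +/-50% of the MLE coordinate with 41 points.  Inner-fit failures are
    recorded as NaN.
    """
    if parameter_name not in _PARAM_INDEX:
        raise DomainError(f"parameter_name must be one of {tuple(_PARAM_INDEX)}")
    _check_mode(mode)
    opts = options or OptimizerOptions()
    w = _as_values(sample)
    full = fit_mle(w, mode=mode, options=opts)
    idx = _PARAM_INDEX[parameter_name]
    mle = np.array([full.estimates.alpha, full.estimates.delta, full.estimates.beta])
    if grid is None:
        lo_default = 0.5 * mle[idx]
        if parameter_name == "beta":
            # stay inside the validity region: below exp(-1) the bracket can
            # go negative and the pseudo-likelihood is not comparable
            lo_default = max(lo_default, opts.beta_lower)
        grid_arr = np.linspace(lo_default, 1.5 * mle[idx], 41)
    else:
        grid_arr = np.asarray(grid, dtype=float)
        if np.any(grid_arr <= 0.0):
            raise DomainError("profile grid values must be positive")
        if parameter_name == "beta" and np.any(grid_arr < opts.beta_lower):
            raise DomainError(
                f"beta profile grid must stay >= exp(-1) ~ {opts.beta_lower:.6f}, "
                "the smallest beta for which the model is a distribution"
            )
    free = [i for i in range(3) if i != idx]
    lowers = [opts.lower, opts.lower, opts.beta_lower]
    log_bounds = [(np.log(lowers[i]), np.log(opts.upper)) for i in free]

    def inner_nll(x: np.ndarray, fixed_value: float):
        ft = np.exp(x)
        theta = np.empty(3)
        theta[idx] = fixed_value
        theta[free[0]], theta[free[1]] = ft
        ll, grad = _loglik_terms(w, theta, mode)
        with np.errstate(over="ignore", invalid="ignore"):
            g = np.nan_to_num(grad[free] * ft, nan=0.0, posinf=1e12, neginf=-1e12)
        return -ll, -g

    values = np.empty(grid_arr.size)
    warm = np.log(np.clip(mle[free], [lowers[i] for i in free], opts.upper))
    for j, gv in enumerate(grid_arr):
        res = minimize(
            inner_nll,
            warm,
            args=(float(gv),),
            jac=True,
            method="L-BFGS-B",
            bounds=log_bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.tol},
        )
        lo = np.array([log_bounds[0][0], log_bounds[1][0]])
        hi = np.array([log_bounds[0][1], log_bounds[1][1]])
        polish = minimize(
            lambda x: inner_nll(np.clip(x, lo, hi), float(gv))[0],
            res.x,
            method="Nelder-Mead",
            options={"maxiter": 1000, "xatol": 1e-9, "fatol": 1e-11},
        )
        fun = min(res.fun, polish.fun)
        if np.isfinite(fun) and fun < _PENALTY / 2:
            values[j] = -float(fun)
            warm = np.clip(polish.x, lo, hi) if polish.fun < res.fun else res.x
        else:
            values[j] = np.nan
    return ProfileCurve(parameter_name, grid_arr, values, full.loglik_max)
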