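"""Comparison lifetime models sharing a common surface.

Five models are addressed by string identifier:

========== ============================================ =========
identifier survival function                            params
========== ============================================ =========
weibull    exp(-delta * w**alpha)                       2
e-weibull  1 - (1 - exp(-delta * w**alpha))**gamma      3
f-weibull  exp(-exp(delta*w - alpha/w))                 2
ef-weibull 1 - (1 - exp(-exp(delta*w - alpha/w)))**gamma 3
nbpf-weibull  beta-power transform of f-weibull         3
========== ============================================ =========

Densities are the analytic negatives of the survival-function derivatives.
Parameters are passed as sequences in canonical order — (alpha, delta) for
the 2-parameter models, (alpha, delta, gamma) for the exponentiated ones,
(alpha, delta, beta) for nbpf-weibull — or as the corresponding dataclass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from . import distributions as dist
from .distributions import FWParams, NBPFParams
from .errors import ConfigurationError, ParameterError
from .inference import FitResult, OptimizerOptions, Sample, _as_values, fit_fweibull, fit_mle

__all__ = [
    "MODEL_NAMES",
    "WeibullParams",
    "ExponentiatedParams",
    "n_params",
    "model_sf",
    "model_pdf",
    "model_loglik",
    "fit_model",
]

MODEL_NAMES = ("weibull", "e-weibull", "f-weibull", "ef-weibull", "nbpf-weibull")

_N_PARAMS = {"weibull": 2, "e-weibull": 3, "f-weibull": 2, "ef-weibull": 3, "nbpf-weibull": 3}

_PARAM_NAMES = {
    "weibull": ("alpha", "delta"),
    "e-weibull": ("alpha", "delta", "gamma"),
    "f-weibull": ("alpha", "delta"),
    "ef-weibull": ("alpha", "delta", "gamma"),
    "nbpf-weibull": ("alpha", "delta", "beta"),
}


@dataclass(frozen=True)
class WeibullParams:
    """Classical Weibull: shape ``alpha``, rate-like coefficient ``delta`` on w**alpha."""

    alpha: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "delta"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0.0:
                raise ParameterError(f"{name} must be positive and finite, got {v!r}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class ExponentiatedParams:
    """Exponentiated model: a base (Weibull or F-Weibull) raised to power ``gamma``."""

    base: Union[WeibullParams, FWParams]
    gamma: float

    def __post_init__(self) -> None:
        g = float(self.gamma)
        if not np.isfinite(g) or g <= 0.0:
            raise ParameterError(f"gamma must be positive and finite, got {g!r}")
        object.__setattr__(self, "gamma", g)


def n_params(model: str) -> int:
    """Number of free parameters of a model identifier."""
    _check_model(model)
    return _N_PARAMS[model]


def param_names(model: str) -> tuple:
    _check_model(model)
    return _PARAM_NAMES[model]


def _check_model(model: str) -> None:
    if model not in MODEL_NAMES:
        raise ConfigurationError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def _coerce(model: str, params) -> np.ndarray:
    _check_model(model)
    if isinstance(params, NBPFParams):
        vec = (params.alpha, params.delta, params.beta)
    elif isinstance(params, ExponentiatedParams):
        vec = (params.base.alpha, params.base.delta, params.gamma)
    elif isinstance(params, (WeibullParams, FWParams)):
        vec = (params.alpha, params.delta)
    else:
        vec = tuple(float(v) for v in params)
    if len(vec) != _N_PARAMS[model]:
        raise ConfigurationError(
            f"model {model!r} takes {_N_PARAMS[model]} parameters {_PARAM_NAMES[model]}, got {len(vec)}"
        )
    arr = np.asarray(vec, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0):
        raise ParameterError(f"all {model!r} parameters must be positive and finite, got {vec}")
    return arr


def _weibull_logsf(w: np.ndarray, alpha: float, delta: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return -delta * w**alpha


def model_sf(w, model: str, params):
    """Survival function of the named model; 1 for w <= 0."""
    vec = _coerce(model, params)
    arr, scalar = dist._prepare_w(w)
    out = np.ones_like(arr)
    pos = arr > 0
    wp = arr[pos]
    if model == "weibull":
        out[pos] = np.exp(_weibull_logsf(wp, *vec))
    elif model == "e-weibull":
        alpha, delta, gamma = vec
        cdf_w = -np.expm1(_weibull_logsf(wp, alpha, delta))
        out[pos] = -np.expm1(gamma * np.log(cdf_w, where=cdf_w > 0, out=np.full_like(cdf_w, -np.inf)))
    elif model == "f-weibull":
        out[pos] = 1.0 - np.asarray(dist.fw_cdf(wp, FWParams(*vec)))
    elif model == "ef-weibull":
        alpha, delta, gamma = vec
        g = np.asarray(dist.fw_cdf(wp, FWParams(alpha, delta)))
        out[pos] = -np.expm1(gamma * np.log(g, where=g > 0, out=np.full_like(g, -np.inf)))
    else:  # nbpf-weibull
        out[pos] = np.asarray(dist.nbpf_sf(wp, NBPFParams(*vec)))
    return dist._ret(out, scalar)


def model_pdf(w, model: str, params):
    """Analytic density of the named model (negative derivative of its SF)."""
    vec = _coerce(model, params)
    arr, scalar = dist._prepare_w(w)
    out = np.zeros_like(arr)
    pos = arr > 0
    wp = arr[pos]
    if model == "weibull":
        alpha, delta = vec
        out[pos] = alpha * delta * wp ** (alpha - 1.0) * np.exp(-delta * wp**alpha)
    elif model == "e-weibull":
        alpha, delta, gamma = vec
        fw = alpha * delta * wp ** (alpha - 1.0) * np.exp(-delta * wp**alpha)
        cdf_w = -np.expm1(_weibull_logsf(wp, alpha, delta))
        out[pos] = gamma * cdf_w ** (gamma - 1.0) * fw
    elif model == "f-weibull":
        out[pos] = np.asarray(dist.fw_pdf(wp, FWParams(*vec)))
    elif model == "ef-weibull":
        alpha, delta, gamma = vec
        g = np.asarray(dist.fw_cdf(wp, FWParams(alpha, delta)))
        out[pos] = gamma * g ** (gamma - 1.0) * np.asarray(dist.fw_pdf(wp, FWParams(alpha, delta)))
    else:
        out[pos] = np.asarray(dist.nbpf_pdf(wp, NBPFParams(*vec), mode="consistent"))
    return dist._ret(out, scalar)


def model_loglik(sample, model: str, params) -> float:
    """Sum of log densities over the sample, computed in log space."""
    vec = _coerce(model, params)
    w = _as_values(sample)
    if model == "weibull":
        alpha, delta = vec
        ll = np.sum(np.log(alpha) + np.log(delta) + (alpha - 1.0) * np.log(w) - delta * w**alpha)
    elif model == "e-weibull":
        alpha, delta, gamma = vec
        logsf = _weibull_logsf(w, alpha, delta)
        cdf_w = -np.expm1(logsf)
        if np.any(cdf_w <= 0.0):
            return -np.inf
        ll = np.sum(
            np.log(gamma)
            + (gamma - 1.0) * np.log(cdf_w)
            + np.log(alpha)
            + np.log(delta)
            + (alpha - 1.0) * np.log(w)
            + logsf
        )
    elif model in ("f-weibull", "ef-weibull"):
        alpha, delta = vec[0], vec[1]
        t = np.clip(delta * w - alpha / w, -dist._T_MAX, dist._T_MAX)
        a = np.exp(t)
        ll = np.sum(np.log(delta + alpha / w**2) + t - a)
        if model == "ef-weibull":
            gamma = vec[2]
            g = -np.expm1(-a)
            if np.any(g <= 0.0):
                return -np.inf
            ll += np.sum(np.log(gamma) + (gamma - 1.0) * np.log(g))
    else:
        from .inference import log_likelihood

        return log_likelihood(w, NBPFParams(*vec), mode="consistent")
    return float(ll)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _fit_generic(w: np.ndarray, model: str, starts, opts: OptimizerOptions) -> FitResult:
    # optimized over log-parameters: automatic positivity, balanced scales
    log_lo, log_hi = np.log(opts.lower), np.log(opts.upper)
    bounds = [(log_lo, log_hi)] * _N_PARAMS[model]

    def nll(x):
        try:
            with np.errstate(over="ignore"):
                ll = model_loglik(w, model, np.exp(np.clip(x, log_lo, log_hi)))
        except (ParameterError, FloatingPointError):
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    best = None
    tried = 0
    for start in starts:
        x0 = np.clip(np.log(np.asarray(start, dtype=float)), log_lo, log_hi)
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.tol},
        )
        tried += 1
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is not None:
        polish = minimize(nll, best.x, method="Nelder-Mead",
                          options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
        if np.isfinite(polish.fun) and polish.fun < best.fun:
            best = polish
            best.x = np.clip(polish.x, log_lo, log_hi)
    if best is None:
        return FitResult(
            estimates={},
            loglik_max=-np.inf,
            converged=False,
            n_obs=w.size,
            mode="consistent",
            restarts_used=tried,
            optimizer_message="all starts failed",
            model=model,
        )
    names = _PARAM_NAMES[model]
    est = {k: float(v) for k, v in zip(names, np.exp(np.clip(best.x, log_lo, log_hi)))}
    return FitResult(
        estimates=est,
        loglik_max=-float(best.fun),
        converged=bool(best.success),
        n_obs=w.size,
        mode="consistent",
        restarts_used=tried,
        optimizer_message=str(best.message),
        model=model,
    )


def _weibull_start(w: np.ndarray) -> np.ndarray:
    # Gumbel log-moment heuristic: shape ~ pi / (sqrt(6) * sd(log w));
    # then E[w**alpha] = 1/delta fixes the rate.
    logw = np.log(w)
    sd = float(np.std(logw))
    alpha0 = np.pi / (np.sqrt(6.0) * sd) if sd > 1e-12 else 1.0
    alpha0 = float(np.clip(alpha0, 0.05, 50.0))
    delta0 = 1.0 / float(np.mean(w**alpha0))
    return np.array([alpha0, delta0])


def fit_model(
    sample,
    model: str,
    mode: str = "consistent",
    options: Optional[OptimizerOptions] = None,
) -> FitResult:
    """Maximum-likelihood fit of any of the five models.

    Starting values: a log-moment heuristic for the Weibull-type base, the
    fitted sub-model for the exponentiated variants (gamma started at
    0.5/1/2, exploiting the gamma=1 nesting), and the nested multi-start
    scheme of :func:`nbpfweibull.inference.fit_mle` for the NBPF-Weibull.
    """
    _check_model(model)
    opts = options or OptimizerOptions()
    w = _as_values(sample)
    if model == "nbpf-weibull":
        return fit_mle(w, mode=mode, options=opts)
    if model == "weibull":
        return _fit_generic(w, model, [_weibull_start(w)], opts)
    if model == "f-weibull":
        res = fit_fweibull(w, opts)
        est = {"alpha": res.estimates.alpha, "delta": res.estimates.delta}
        return FitResult(
            estimates=est,
            loglik_max=res.loglik_max,
            converged=res.converged,
            n_obs=res.n_obs,
            mode="consistent",
            optimizer_message=res.optimizer_message,
            model="f-weibull",
        )
    if model == "e-weibull":
        base = _fit_generic(w, "weibull", [_weibull_start(w)], opts)
        a0, d0 = base.estimates["alpha"], base.estimates["delta"]
        starts = [np.array([a0, d0, g0]) for g0 in (0.5, 1.0, 2.0)]
        return _fit_generic(w, model, starts, opts)
    # ef-weibull
    base = fit_fweibull(w, opts)
    a0, d0 = base.estimates.alpha, base.estimates.delta
    starts = [np.array([a0, d0, g0]) for g0 in (0.5, 1.0, 2.0)]
    return _fit_generic(w, model, starts, opts)
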