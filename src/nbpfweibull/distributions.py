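"""The flexible Weibull base model and its beta-power extension.

The flexible Weibull (F-Weibull) distribution is a two-parameter lifetime
model with CDF

    G(w; alpha, delta) = 1 - exp(-exp(delta*w - alpha/w)),   w > 0,

whose hazard can be non-monotone, unlike the classical Weibull.  The
beta-power transform maps a base CDF ``G`` to

    F(w) = (beta**G + G - 1) / beta,

adding one dimensionless shape parameter ``beta`` and reducing to the base
model exactly at ``beta = 1``.  Applying the transform to the F-Weibull
yields the three-parameter beta-power flexible Weibull (NBPF-Weibull)
distribution implemented here: CDF, survival, density, hazard, cumulative
hazard, quantile, and random sampling.

Two density brackets are exposed through the ``mode`` argument:

``consistent``
    f(w) = g(w) * (1 + beta**G(w) * log(beta)) / beta — the exact derivative
    of the CDF above (``g`` is the F-Weibull density).  This is the default
    everywhere.
``as_printed``
    f(w) = g(w) * (1 + G(w) * log(beta)) / beta — a variant bracket that is
    *not* the CDF derivative and integrates to (1 + log(beta)/2)/beta rather
    than 1.  It is retained so the two parameterizations of the likelihood
    can be compared on the same data.

All functions are vectorized over ``w`` and accept scalars or arrays;
scalars in give Python floats out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import DomainError, NumericalError, ParameterError

__all__ = [
    "FWParams",
    "NBPFParams",
    "PDF_MODES",
    "fw_cdf",
    "fw_pdf",
    "fw_quantile",
    "nbpf_cdf",
    "nbpf_sf",
    "nbpf_pdf",
    "nbpf_hf",
    "nbpf_chf",
    "nbpf_quantile",
    "nbpf_rvs",
]

#: Valid density-bracket modes.
PDF_MODES = ("consistent", "as_printed")

# exp() overflows above ~709.8; the exponent t = delta*w - alpha/w is clamped
# so that exp(t) stays finite (exp(t - exp(t)) then underflows cleanly to 0).
_T_MAX = 700.0

ArrayLike = Union[float, np.ndarray]


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0.0:
        raise ParameterError(f"{name} must be a positive finite real, got {value!r}")
    return value


@dataclass(frozen=True)
class FWParams:
    """F-Weibull parameters: ``alpha`` (time units), ``delta`` (1/time)."""

    alpha: float
    delta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _positive("alpha", self.alpha))
        object.__setattr__(self, "delta", _positive("delta", self.delta))


@dataclass(frozen=True)
class NBPFParams:
    """NBPF-Weibull parameters.

    ``alpha`` and ``delta`` are the F-Weibull base parameters; ``beta`` is the
    dimensionless transform parameter.  ``beta = 1`` recovers the F-Weibull
    sub-model exactly.
    """

    alpha: float
    delta: float
    beta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _positive("alpha", self.alpha))
        object.__setattr__(self, "delta", _positive("delta", self.delta))
        object.__setattr__(self, "beta", _positive("beta", self.beta))

    @property
    def base(self) -> FWParams:
        return FWParams(self.alpha, self.delta)


def _check_mode(mode: str) -> str:
    if mode not in PDF_MODES:
        raise DomainError(f"mode must be one of {PDF_MODES}, got {mode!r}")
    return mode


def _prepare_w(w: ArrayLike) -> tuple[np.ndarray, bool]:
    arr = np.asarray(w, dtype=float)
    scalar = arr.ndim == 0
    return np.atleast_1d(arr), scalar


def _ret(out: np.ndarray, scalar: bool) -> ArrayLike:
    return float(out[0]) if scalar else out


def _exponent(w: np.ndarray, alpha: float, delta: float) -> np.ndarray:
    """t = delta*w - alpha/w for w > 0, clamped for exp() safety."""
    return np.clip(delta * w - alpha / w, -_T_MAX, _T_MAX)


# ---------------------------------------------------------------------------
# F-Weibull base model
# ---------------------------------------------------------------------------


def fw_cdf(w: ArrayLike, p: FWParams) -> ArrayLike:
    """F-Weibull CDF G(w) = 1 - exp(-exp(delta*w - alpha/w)); 0 for w <= 0."""
    arr, scalar = _prepare_w(w)
    out = np.zeros_like(arr)
    pos = arr > 0
    t = _exponent(arr[pos], p.alpha, p.delta)
    out[pos] = -np.expm1(-np.exp(t))
    return _ret(out, scalar)


def fw_pdf(w: ArrayLike, p: FWParams) -> ArrayLike:
    """F-Weibull density (delta + alpha/w^2) * exp(t) * exp(-exp(t)); 0 for w <= 0."""
    arr, scalar = _prepare_w(w)
    out = np.zeros_like(arr)
    pos = arr > 0
    wp = arr[pos]
    t = _exponent(wp, p.alpha, p.delta)
    a = np.exp(t)
    # A * exp(-A) computed as exp(t - A) to avoid 0 * inf in the far tail
    out[pos] = (p.delta + p.alpha / wp**2) * np.exp(t - a)
    return _ret(out, scalar)


def fw_quantile(u: ArrayLike, p: FWParams) -> ArrayLike:
    """Closed-form F-Weibull quantile.

    Setting c = log(-log(1-u)), the CDF inverts through the quadratic
    delta*w^2 - c*w - alpha = 0, whose positive root is
    w = (c + sqrt(c^2 + 4*alpha*delta)) / (2*delta).
    """
    arr, scalar = _prepare_w(u)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise DomainError("probabilities must lie strictly inside (0, 1)")
    c = np.log(-np.log1p(-arr))
    q = 4.0 * p.alpha * p.delta
    root = np.sqrt(c * c + q)
    # (c + root) cancels badly when c is large and negative; rationalize there.
    out = np.where(c >= 0.0, (c + root) / (2.0 * p.delta), 2.0 * p.alpha / (root - c))
    return _ret(out, scalar)


# ---------------------------------------------------------------------------
# NBPF-Weibull
# ---------------------------------------------------------------------------


def nbpf_cdf(w: ArrayLike, p: NBPFParams) -> ArrayLike:
    """NBPF-Weibull CDF F(w) = (beta**G + G - 1)/beta with G the F-Weibull CDF."""
    arr, scalar = _prepare_w(w)
    g = np.atleast_1d(np.asarray(fw_cdf(arr, p.base)))
    # expm1 keeps precision where beta**G - 1 and G are both tiny
    out = (np.expm1(g * np.log(p.beta)) + g) / p.beta
    return _ret(np.clip(out, 0.0, 1.0), scalar)


def nbpf_sf(w: ArrayLike, p: NBPFParams) -> ArrayLike:
    """Survival S(w) = (beta - beta**G + (1 - G))/beta, computed tail-stably."""
    arr, scalar = _prepare_w(w)
    out = np.ones_like(arr)
    pos = arr > 0
    wp = arr[pos]
    t = _exponent(wp, p.alpha, p.delta)
    a = np.exp(t)
    one_minus_g = np.exp(-a)
    g = -np.expm1(-a)
    lb = np.log(p.beta)
    # beta - beta**G = -beta * expm1((G-1)*log beta)
    out[pos] = -np.expm1((g - 1.0) * lb) + one_minus_g / p.beta
    return _ret(np.clip(out, 0.0, 1.0), scalar)


def nbpf_pdf(w: ArrayLike, p: NBPFParams, mode: str = "consistent") -> ArrayLike:
    """NBPF-Weibull density; ``mode`` selects the bracket (see module docstring)."""
    _check_mode(mode)
    arr, scalar = _prepare_w(w)
    out = np.zeros_like(arr)
    pos = arr > 0
    wp = arr[pos]
    t = _exponent(wp, p.alpha, p.delta)
    a = np.exp(t)
    g = -np.expm1(-a)
    base = (p.delta + p.alpha / wp**2) * np.exp(t - a)
    lb = np.log(p.beta)
    if mode == "consistent":
        bracket = 1.0 + lb * np.exp(g * lb)
    else:
        bracket = 1.0 + lb * g
    out[pos] = base * bracket / p.beta
    return _ret(out, scalar)


def nbpf_hf(w: ArrayLike, p: NBPFParams, mode: str = "consistent") -> ArrayLike:
    """Hazard h = f/S; returns +inf where the survival function underflows to 0."""
    _check_mode(mode)
    arr, scalar = _prepare_w(w)
    f = np.atleast_1d(np.asarray(nbpf_pdf(arr, p, mode)))
    s = np.atleast_1d(np.asarray(nbpf_sf(arr, p)))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0.0, f / s, np.inf)
    return _ret(out, scalar)


def nbpf_chf(w: ArrayLike, p: NBPFParams) -> ArrayLike:
    """Cumulative hazard H(w) = -log S(w); 0 at the origin, +inf where S = 0."""
    arr, scalar = _prepare_w(w)
    s = np.atleast_1d(np.asarray(nbpf_sf(arr, p)))
    with np.errstate(divide="ignore"):
        out = -np.log(s)
    return _ret(out, scalar)


def _transform_inverse(prob: np.ndarray, beta: float) -> np.ndarray:
    """Solve beta**G + G - 1 = beta*prob for G in [0, 1].

    Vectorized Newton iteration safeguarded by bisection on the bracket
    [0, 1]; k(0) = -beta*prob <= 0 <= k(1) = beta*(1 - prob) guarantees a
    root.  Converges to 1e-12 in G.
    """
    if beta == 1.0:
        return prob.copy()
    lb = np.log(beta)
    target = beta * prob

    def k(g: np.ndarray) -> np.ndarray:
        return np.expm1(g * lb) + g - target

    lo = np.zeros_like(prob)
    hi = np.ones_like(prob)
    x = prob.copy()
    for _ in range(200):
        fx = k(x)
        lo = np.where(fx <= 0.0, x, lo)
        hi = np.where(fx >= 0.0, x, hi)
        deriv = 1.0 + lb * np.exp(x * lb)
        with np.errstate(divide="ignore", invalid="ignore"):
            newton = x - fx / deriv
        mid = 0.5 * (lo + hi)
        inside = (newton > lo) & (newton < hi) & np.isfinite(newton)
        x_new = np.where(inside, newton, mid)
        if np.max(np.abs(x_new - x)) < 1e-13:
            x = x_new
            break
        x = x_new
    if np.max(np.abs(k(x))) > 1e-9 * max(1.0, beta):  # pragma: no cover
        raise NumericalError("quantile inner root-finder failed to converge")
    return x


def nbpf_quantile(prob: ArrayLike, p: NBPFParams) -> ArrayLike:
    """NBPF-Weibull quantile: invert the beta-power layer, then the base CDF."""
    arr, scalar = _prepare_w(prob)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise DomainError("probabilities must lie strictly inside (0, 1)")
    g = _transform_inverse(arr, p.beta)
    out = np.atleast_1d(np.asarray(fw_quantile(g, p.base)))
    return _ret(out, scalar)


def nbpf_rvs(
    n: int,
    p: NBPFParams,
    seed: Union[int, np.random.Generator, np.random.SeedSequence, None] = None,
) -> np.ndarray:
    """Draw ``n`` variates by inverse-transform sampling.

    Uniforms are drawn from the open interval (0, 1) and pushed through the
    quantile function; identical seeds give identical samples.
    """
    n = int(n)
    if n < 1:
        raise DomainError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    tiny = np.finfo(float).tiny
    u = np.clip(u, tiny, 1.0 - np.finfo(float).epsneg)
    return np.asarray(nbpf_quantile(u, p))
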