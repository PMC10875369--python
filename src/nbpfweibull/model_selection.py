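"""Information-criterion model comparison and goodness-of-fit diagnostics.

Four penalized-likelihood criteria rank candidate models (lower = better),
with ``m`` free parameters, ``n`` observations and maximized log-likelihood
``loglik``:

    AIC  = 2m - 2*loglik
    BIC  = m*log(n) - 2*loglik
    CAIC = 2nm/(n - m - 1) - 2*loglik      (small-sample corrected AIC)
    HQIC = 2m*log(log(n)) - 2*loglik

:func:`compare_models` fits any subset of the five registered models to one
sample and tabulates the criteria; :func:`diagnostic_points` computes the
plot-ready empirical-CDF, PP, QQ and fitted-curve point sets behind the
usual goodness-of-fit panels.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .competitors import MODEL_NAMES, fit_model, n_params
from .distributions import NBPFParams, nbpf_cdf, nbpf_pdf, nbpf_quantile, nbpf_sf
from .errors import DomainError
from .inference import FitResult, OptimizerOptions, Sample, _as_values

__all__ = [
    "ICRecord",
    "ComparisonTable",
    "DiagnosticPoints",
    "information_criteria",
    "compare_models",
    "diagnostic_points",
]


@dataclass(frozen=True)
class ICRecord:
    """One model's information-criterion row."""

    model_name: str
    m: int
    n: int
    loglik: float
    aic: float
    caic: float
    bic: float
    hqic: float
    converged: bool = True


@dataclass(frozen=True)
class ComparisonTable:
    """Fitted records plus a deterministic ranking by ascending AIC."""

    records: list
    ranking: list
    fits: dict

    def to_dataframe(self) -> pd.DataFrame:
        rank_of = {name: i + 1 for i, name in enumerate(self.ranking)}
        rows = []
        for rec in self.records:
            row = asdict(rec)
            row["rank"] = rank_of.get(rec.model_name)
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.rename(columns={"model_name": "model"})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = self.to_dataframe().to_dict(orient="records")
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return None

    @property
    def best(self) -> str:
        return self.ranking[0]


def information_criteria(loglik: float, m: int, n: int, model_name: str = "") -> ICRecord:
    """Compute AIC/CAIC/BIC/HQIC from a maximized log-likelihood.

    Requires ``n > m + 1`` (CAIC denominator) and ``n >= 3`` (log log n).
    """
    m = int(m)
    n = int(n)
    if m < 1:
        raise DomainError(f"parameter count m must be >= 1, got {m}")
    if n <= m + 1:
        raise DomainError(f"CAIC requires n > m + 1; got n={n}, m={m}")
    if n < 3:
        raise DomainError(f"HQIC requires n >= 3 (log log n), got n={n}")
    loglik = float(loglik)
    if not math.isfinite(loglik):
        raise DomainError("log-likelihood must be finite")
    aic = 2.0 * m - 2.0 * loglik
    bic = m * math.log(n) - 2.0 * loglik
    caic = 2.0 * n * m / (n - m - 1.0) - 2.0 * loglik
    hqic = 2.0 * m * math.log(math.log(n)) - 2.0 * loglik
    return ICRecord(model_name=model_name, m=m, n=n, loglik=loglik, aic=aic, caic=caic, bic=bic, hqic=hqic)


def compare_models(
    sample,
    model_names: Sequence[str] = MODEL_NAMES,
    mode: str = "consistent",
    options: Optional[OptimizerOptions] = None,
) -> ComparisonTable:
    """Fit each named model to the sample and rank by ascending AIC.

    Models whose fit fails are kept in ``records`` with ``converged=False``
    and NaN criteria but excluded from the ranking.  Ties are broken by
    (AIC, BIC, model name).
    """
    names = list(model_names)
    if len(names) < 2:
        raise DomainError("compare_models needs at least two model names")
    w = _as_values(sample)
    n = w.size
    records = []
    fits = {}
    for name in names:
        fit = fit_model(w, name, mode=mode, options=options)
        fits[name] = fit
        if np.isfinite(fit.loglik_max):
            rec = information_criteria(fit.loglik_max, n_params(name), n, model_name=name)
            rec = ICRecord(**{**asdict(rec), "converged": fit.converged})
        else:
            rec = ICRecord(name, n_params(name), n, float("nan"), float("nan"),
                           float("nan"), float("nan"), float("nan"), converged=False)
        records.append(rec)
    rankable = [r for r in records if math.isfinite(r.aic)]
    ranking = [r.model_name for r in sorted(rankable, key=lambda r: (r.aic, r.bic, r.model_name))]
    return ComparisonTable(records=records, ranking=ranking, fits=fits)


@dataclass(frozen=True)
class DiagnosticPoints:
    """Plot-ready point sets for goodness-of-fit panels.

    ``ecdf_*`` are the empirical CDF step coordinates (sorted data, i/n);
    ``pp_*`` pair fitted CDF values with Hazen plotting positions
    (i - 0.5)/n; ``qq_*`` pair fitted quantiles at those positions with the
    order statistics; ``grid_*`` are fitted PDF/CDF/SF curves on an even
    grid spanning the sample range.
    """

    ecdf_w: np.ndarray
    ecdf_p: np.ndarray
    pp_theoretical: np.ndarray
    pp_empirical: np.ndarray
    qq_theoretical: np.ndarray
    qq_empirical: np.ndarray
    grid_w: np.ndarray
    grid_pdf: np.ndarray
    grid_cdf: np.ndarray
    grid_sf: np.ndarray


def diagnostic_points(sample, fit: FitResult, n_grid: int = 200) -> DiagnosticPoints:
    """Diagnostic point sets for a converged NBPF-Weibull fit."""
    if not fit.converged:
        raise DomainError("diagnostic_points requires a converged fit")
    params = fit.estimates
    if not isinstance(params, NBPFParams):
        params = NBPFParams(**fit.params_dict())
    w = np.sort(_as_values(sample))
    n = w.size
    positions = (np.arange(1, n + 1) - 0.5) / n
    ecdf_p = np.arange(1, n + 1) / n
    grid = np.linspace(w[0], w[-1], n_grid)
    return DiagnosticPoints(
        ecdf_w=w,
        ecdf_p=ecdf_p,
        pp_theoretical=np.asarray(nbpf_cdf(w, params)),
        pp_empirical=positions,
        qq_theoretical=np.asarray(nbpf_quantile(positions, params)),
        qq_empirical=w,
        grid_w=grid,
        grid_pdf=np.asarray(nbpf_pdf(grid, params, mode=fit.mode)),
        grid_cdf=np.asarray(nbpf_cdf(grid, params)),
        grid_sf=np.asarray(nbpf_sf(grid, params)),
    )
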