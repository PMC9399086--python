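"""Posterior summaries: shortest HDI, WAIC, and convergence checks."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ..exceptions import DataValidationError

__all__ = ["HDInterval", "hdi", "WAICResult", "waic", "compare_waic",
           "check_convergence"]


@dataclass(frozen=True)
class HDInterval:
    lower: float
    upper: float
    mass: float = 0.95

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def hdi(samples, mass: float = 0.95) -> HDInterval:
    """Shortest interval containing ``ceil(mass * n)`` sorted samples.

    Assumes a unimodal posterior (sorted-window algorithm).
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size == 0:
        raise DataValidationError("hdi needs at least one sample")
    if not np.all(np.isfinite(x)):
        raise DataValidationError("hdi input contains non-finite values")
    if not 0 < mass <= 1:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    n = x.size
    k = int(math.ceil(mass * n))
    if k >= n:
        return HDInterval(float(x[0]), float(x[-1]), mass)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HDInterval(float(x[i]), float(x[i + k - 1]), mass)


@dataclass(frozen=True)
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    se_waic: float

    def to_dict(self) -> dict:
        return {"lppd": self.lppd, "p_waic": self.p_waic,
                "waic": self.waic, "se_waic": self.se_waic}


def _pointwise_waic(loglik: np.ndarray):
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("loglik must be (draws, trials)")
    S = loglik.shape[0]
    if S < 2:
        raise DataValidationError("WAIC needs at least 2 draws (variance undefined)")
    if not np.all(np.isfinite(loglik)):
        raise DataValidationError("loglik matrix contains non-finite values")
    lppd_i = logsumexp(loglik, axis=0) - np.log(S)
    p_i = np.var(loglik, axis=0, ddof=1)
    return lppd_i, p_i


def waic(loglik: np.ndarray) -> WAICResult:
    """Widely applicable information criterion from a draws x trials
    log-likelihood matrix: ``-2 * (lppd - p_waic)``, lower is better."""
    lppd_i, p_i = _pointwise_waic(loglik)
    elpd_i = lppd_i - p_i
    n = elpd_i.size
    se = float(np.sqrt(n * np.var(-2 * elpd_i, ddof=1))) if n > 1 else 0.0
    return WAICResult(
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        waic=float(-2 * (lppd_i.sum() - p_i.sum())),
        se_waic=se,
    )


def compare_waic(loglik_a: np.ndarray, loglik_b: np.ndarray) -> dict:
    """WAIC difference (a - b) with a paired trial-wise standard error."""
    la, pa = _pointwise_waic(loglik_a)
    lb, pb = _pointwise_waic(loglik_b)
    if la.size != lb.size:
        raise DataValidationError("models were evaluated on different trial counts")
    wa = -2 * (la - pa)
    wb = -2 * (lb - pb)
    d = wa - wb
    n = d.size
    return {
        "waic_a": float(wa.sum()),
        "waic_b": float(wb.sum()),
        "d_waic": float(d.sum()),
        "se_d_waic": float(np.sqrt(n * np.var(d, ddof=1))) if n > 1 else 0.0,
    }


def check_convergence(posterior, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split R-hat and effective sample size per scalar parameter.

    Uses ArviZ's rank-normalized diagnostics.  With a single chain, R-hat is
    omitted (NaN) and a warning is issued.
    """
    import arviz as az

    draws = posterior.draws  # (chains, draws, dim)
    names = posterior.parameter_names
    chains = draws.shape[0]
    rows = []
    single = chains < 2
    if single:
        warnings.warn("single chain: R-hat omitted", stacklevel=2)
    for j, name in enumerate(names):
        arr = draws[:, :, j]
        rhat = float("nan") if single else float(az.rhat(arr.astype(float)))
        ess = float(az.ess(arr.astype(float)))
        rows.append({"parameter": name, "rhat": rhat, "ess": ess,
                     "flagged": (not single) and rhat > rhat_threshold})
    return pd.DataFrame(rows)
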