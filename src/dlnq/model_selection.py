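"""Candidate-distribution fitting for the positive part, compared by AIC.

Candidates: normal, lognormal, gamma, exponential — all fitted by maximum
likelihood on the positive observations only (the zero mass is modelled
separately as binomial).  Normal and lognormal use the closed-form MLE with
the ML variance (divisor n); the exponential rate is 1/mean (one free
parameter); gamma is fitted numerically.  AIC = 2 * n_params - 2 * loglik.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import GroupData

__all__ = ["FitResult", "fit_candidates", "select_min_aic", "aic_table"]

DISTRIBUTIONS = ("normal", "lognormal", "gamma", "exponential")


@dataclass(frozen=True)
class FitResult:
    distribution: str
    params: dict
    loglik: float
    n_params: int

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


def _fit_normal(x: np.ndarray) -> FitResult:
    n = x.size
    mu = float(np.mean(x))
    s2 = float(np.var(x))  # ML divisor n
    ll = -n / 2 * math.log(2 * math.pi * s2) - n / 2
    return FitResult("normal", {"mu": mu, "sigma2": s2}, ll, 2)


def _fit_lognormal(x: np.ndarray) -> FitResult:
    n = x.size
    lg = np.log(x)
    mu = float(np.mean(lg))
    s2 = float(np.var(lg))
    ll = -n / 2 * math.log(2 * math.pi * s2) - n / 2 - float(np.sum(lg))
    return FitResult("lognormal", {"mu": mu, "sigma2": s2}, ll, 2)


def _fit_gamma(x: np.ndarray) -> FitResult:
    shape, _, scale = stats.gamma.fit(x, floc=0)
    ll = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
    return FitResult("gamma", {"shape": shape, "rate": 1.0 / scale}, ll, 2)


def _fit_exponential(x: np.ndarray) -> FitResult:
    n = x.size
    xbar = float(np.mean(x))
    ll = -n * math.log(xbar) - n
    return FitResult("exponential", {"rate": 1.0 / xbar}, ll, 1)


_FITTERS = {
    "normal": _fit_normal,
    "lognormal": _fit_lognormal,
    "gamma": _fit_gamma,
    "exponential": _fit_exponential,
}


def fit_candidates(positives) -> list[FitResult]:
    """ML fits of the four candidate distributions to positive data."""
    x = np.asarray(positives, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 positive values")
    if np.any(x <= 0):
        raise ValueError("fits are on positive values only")
    return [_FITTERS[d](x) for d in DISTRIBUTIONS]


def select_min_aic(fits: Sequence[FitResult]) -> FitResult:
    """Smallest-AIC fit; ties broken by fewer parameters, then input order."""
    if not fits:
        raise ValueError("no fits supplied")
    return min(enumerate(fits), key=lambda t: (t[1].aic, t[1].n_params, t[0]))[1]


def aic_table(groups: Sequence[GroupData]):
    """AIC of each candidate for each group, as a pandas DataFrame.

    Rows are distributions, columns group labels; the ``selected`` row
    flags the minimum-AIC candidate per group.
    """
    import pandas as pd

    cols = {}
    selected = {}
    for g in groups:
        fits = fit_candidates(g.positives())
        cols[g.label] = {f.distribution: f.aic for f in fits}
        selected[g.label] = select_min_aic(fits).distribution
    df = pd.DataFrame(cols).reindex(list(DISTRIBUTIONS))
    df.loc["selected"] = pd.Series(selected)
    return df
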