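"""Bayesian highest-posterior-density intervals for the common percentile.

Both variants start from the standard conjugate posteriors for the positive
lognormal part under the noninformative reference prior:

    sigma2 | y ~ InverseGamma((n1-1)/2, (n1-1) s2 / 2)
    mu | sigma2, y ~ Normal(ybar1, sigma2 / n1)

and differ in how the percentile draw is formed:

BS1 ("fiducial quantity"): the zero probability is drawn from the truncated
Beta(n0+0.5, n1+0.5) fiducial construction and the percentile draw has the
same Student-type pivot structure as the FGCI.

BS2 ("approximate fiducial distribution"): the percentile draw is
deterministic given (mu, sigma2) — mu + sqrt(sigma2/n1) * t*, with t* the
(1 - alpha) noncentral-t quantile at the plug-in eta_hat; randomness enters
only through the posterior of (mu, sigma2).  By construction this is an
upper-tolerance-limit style draw and sits above the true percentile on
average.

Draws are combined across groups by inverse-variance weighting (variance
formulas at the drawn parameter values) and the interval is the shortest
empirical HPD window of the combined draws, exponentiated.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    IntervalResult,
    PercentileAtZeroMass,
    PercentileSpec,
    eta,
    var_lambda,
    var_s2_1,
    var_ybar1,
)
from .data import GroupSummary
from .fgci import _divisor, truncated_beta_delta

__all__ = [
    "draw_sigma2_mu",
    "bs1_lambda_draw",
    "bs2_lambda_draw",
    "hpd",
    "bayes_interval",
]

VARIANTS = ("bs1", "bs2")


def draw_sigma2_mu(summary: GroupSummary, m: int, rng: np.random.Generator):
    """Joint posterior draws of (sigma2, mu) for one group."""
    df = summary.n1 - 1
    # InverseGamma(a, scale=b) == 1 / Gamma(a, scale=1/b)
    sigma2 = 1.0 / rng.gamma(shape=df / 2.0, scale=2.0 / (df * summary.s2_1), size=m)
    mu = rng.normal(summary.ybar1, np.sqrt(sigma2 / summary.n1))
    return sigma2, mu


def bs1_lambda_draw(
    mu,
    sigma2,
    summary: GroupSummary,
    p: float,
    z_draw,
    u_draw,
    v,
    pivot_scaling: str = "normalized",
):
    """Percentile draw with fiducial zero-probability (BS1)."""
    q_delta = truncated_beta_delta(summary.n0, summary.n1, p, v)
    q_eta = (p - q_delta) / (1.0 - q_delta)
    d = _divisor(u_draw, summary.n1, pivot_scaling)
    zq = stats.norm.ppf(np.asarray(q_eta, dtype=float))
    return (
        np.asarray(mu)
        + np.sqrt(np.asarray(sigma2)) / math.sqrt(summary.n1)
        * (np.asarray(z_draw) + zq * math.sqrt(summary.n1)) / d
    )


def bs2_t_star(summary: GroupSummary, spec: PercentileSpec) -> float:
    """Noncentral-t factor of the BS2 draw; constant for a given group."""
    e = eta(spec.p, summary.delta_hat)
    z_eta = float(stats.norm.ppf(e))
    return float(
        stats.nct.ppf(1 - spec.alpha, summary.n1 - 1, z_eta * math.sqrt(summary.n1))
    )


def bs2_lambda_draw(mu, sigma2, summary: GroupSummary, spec: PercentileSpec):
    """Percentile draw with plug-in zero-probability (BS2)."""
    t_star = bs2_t_star(summary, spec)
    return np.asarray(mu) + np.sqrt(np.asarray(sigma2)) / math.sqrt(summary.n1) * t_star


def hpd(draws, alpha: float) -> tuple[float, float]:
    """Shortest empirical 100(1-alpha)% interval of a draw set.

    Sorts the draws and slides a window of length ceil((1-alpha) * m),
    returning the first window of minimal width on ties.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 draws")
    w = math.ceil((1 - alpha) * m)
    w = min(max(w, 2), m)
    widths = x[w - 1:] - x[: m - w + 1]
    j = int(np.argmin(widths))  # argmin takes the first minimal window
    return float(x[j]), float(x[j + w - 1])


def bayes_draws(
    summaries: Sequence[GroupSummary],
    spec: PercentileSpec,
    m: int,
    variant: str,
    rng: np.random.Generator,
    variance_form: str = "eq41",
    pivot_scaling: str = "normalized",
) -> np.ndarray:
    """Combined posterior draws of the common log percentile."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    for s in summaries:
        if variant == "bs2" and spec.p <= s.delta_hat:
            raise PercentileAtZeroMass(
                f"group {s.label!r}: p={spec.p} <= delta_hat={s.delta_hat:.4f}"
            )
    num = np.zeros(m)
    den = np.zeros(m)
    for s in summaries:
        sigma2, mu = draw_sigma2_mu(s, m, rng)
        if variant == "bs1":
            z = rng.standard_normal(m)
            u = rng.chisquare(s.n1 - 1, m)
            v = rng.uniform(0.0, 1.0, m)
            lam = bs1_lambda_draw(mu, sigma2, s, spec.p, z, u, v, pivot_scaling)
        else:
            lam = bs2_lambda_draw(mu, sigma2, s, spec)
        var = var_lambda(
            lam,
            var_ybar1(mu, sigma2, s.n1),
            var_s2_1(mu, sigma2, s.n1),
            spec.p,
            variance_form,
        )
        num += lam / var
        den += 1.0 / var
    return num / den


def bayes_interval(
    summaries: Sequence[GroupSummary],
    spec: PercentileSpec,
    m: int = 1000,
    variant: str = "bs1",
    rng: np.random.Generator | int | None = None,
    variance_form: str = "eq41",
    pivot_scaling: str = "normalized",
) -> IntervalResult:
    """HPD interval for the common percentile (variant "bs1" or "bs2")."""
    if m < 100:
        raise ValueError("m must be >= 100 for a stable HPD estimate")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = bayes_draws(summaries, spec, m, variant, gen, variance_form, pivot_scaling)
    lo, hi = hpd(draws, spec.alpha)
    return IntervalResult(
        method=variant,
        log_L=lo,
        log_U=hi,
        p=spec.p,
        alpha=spec.alpha,
        m=m,
        seed=int(seed) if seed is not None else None,
    )
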