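"""Per-group percentile estimator, asymptotic variances and the
precision-weighted common percentile.

Model: observations are 0 with probability ``delta'`` and lognormal(mu,
sigma2) otherwise.  For a target percentile ``p > delta'`` the p-th quantile
of the mixture is ``exp(lambda_p)`` with

    lambda_p = mu + Phi^{-1}(eta) * sigma,      eta = (p - delta') / (1 - delta'),

i.e. the percentile level is first renormalised to the positive component.
For ``p <= delta'`` the quantile is 0 and the log-scale parameter is
undefined; those cases raise :class:`PercentileAtZeroMass`.

Several groups sharing a common percentile are combined by inverse-variance
weighting of the per-group log-scale estimates.  Two printed forms of the
variance of the estimator circulate (they differ in whether the squared
normal quantile multiplies inside or outside the leading factor); both are
implemented behind the ``form`` switch, ``"eq41"`` being the default used
throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data import GroupSummary

__all__ = [
    "PercentileSpec",
    "PercentileAtZeroMass",
    "IntervalResult",
    "GroupPercentileEstimate",
    "CommonPercentileEstimate",
    "eta",
    "lambda_hat",
    "var_ybar1",
    "var_s2_1",
    "var_lambda",
    "weighted_common",
    "common_percentile_estimate",
]

VARIANCE_FORMS = ("eq8", "eq41")


class PercentileAtZeroMass(ValueError):
    """Raised when the target percentile falls inside the zero point mass."""


@dataclass(frozen=True)
class PercentileSpec:
    """Target percentile ``p`` and significance level ``alpha``."""

    p: float = 0.95
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def z_p(self) -> float:
        return float(stats.norm.ppf(self.p))


@dataclass(frozen=True)
class IntervalResult:
    """A two-sided confidence interval for the common percentile.

    Limits are reported both on the original scale (``L``, ``U``) and on the
    log scale; ``L = exp(log_L)`` and ``U = exp(log_U)``.
    """

    method: str
    log_L: float
    log_U: float
    p: float
    alpha: float
    m: int | None = None
    seed: int | None = None

    @property
    def L(self) -> float:
        return math.exp(self.log_L)

    @property
    def U(self) -> float:
        return math.exp(self.log_U)

    @property
    def length(self) -> float:
        return self.U - self.L

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "L": self.L,
            "U": self.U,
            "length": self.length,
            "log_L": self.log_L,
            "log_U": self.log_U,
            "p": self.p,
            "alpha": self.alpha,
        }
        if self.m is not None:
            d["m"] = self.m
        if self.seed is not None:
            d["seed"] = self.seed
        return d


def eta(p: float, delta_prime: float) -> float:
    """Conditional exceedance level (p - delta') / (1 - delta')."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if p <= delta_prime:
        raise PercentileAtZeroMass(
            f"percentile at zero mass: p={p} <= delta'={delta_prime}; quantile is 0"
        )
    return (p - delta_prime) / (1.0 - delta_prime)


def lambda_hat(summary: GroupSummary, p: float) -> float:
    """Log-scale percentile estimate ybar1 + Phi^{-1}(eta_hat) * s1."""
    e = eta(p, summary.delta_hat)
    return summary.ybar1 + float(stats.norm.ppf(e)) * math.sqrt(summary.s2_1)


def var_ybar1(mu, sigma2, n1):
    """Asymptotic variance attached to the positive-part log mean.

    Evaluated term by term exactly as printed in the source formulas; note
    the exp(mu) factors place it on the back-transformed scale.  Accepts
    scalars or arrays (vectorised over fiducial/posterior draws).
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    denom = 2.0 * (n1 + 4.0) * (n1 - 1.0)
    # extreme draws may overflow to inf; downstream weighting treats an
    # infinite variance as weight zero, which is the right limit
    with np.errstate(over="ignore"):
        growth = np.exp((n1 - 1.0) * sigma2 / (denom + 3.0 * sigma2))
        t1 = np.exp(mu) ** 2
        t2 = sigma2 / n1 + 1.0
        t3 = growth**2
        t4 = (2.0 * (n1 - 1.0) * (sigma2**2 / n1)) / (denom + 6.0 * sigma2**2 / n1) + 1.0
        t5 = (np.exp(mu) * growth) ** 2
        out = t1 * t2 * t3 * t4 - t5
    return out if out.ndim else float(out)


def var_s2_1(mu, sigma2, n1):
    """Asymptotic variance attached to the positive-part log variance."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    with np.errstate(over="ignore"):
        out = (2.0 * sigma2 / n1 * np.exp(4.0 * mu + 2.0 * sigma2)) * (
            2.0 * (np.exp(sigma2) - 1.0) ** 2
            + sigma2 * (2.0 * np.exp(sigma2) - 1.0) ** 2
        )
    return out if out.ndim else float(out)


def var_lambda(lambda_value, var_ybar, var_s2, p: float, form: str = "eq41"):
    """Variance of the log-scale percentile estimate.

    ``form="eq41"``: lambda^2 * Var(Ybar) + z_p^2 * Var(S^2)
    ``form="eq8"`` : lambda^2 * (Var(Ybar) + z_p^2 * Var(S^2))
    """
    if form not in VARIANCE_FORMS:
        raise ValueError(f"unknown variance form {form!r}; expected one of {VARIANCE_FORMS}")
    zp2 = float(stats.norm.ppf(p)) ** 2
    lam = np.asarray(lambda_value, dtype=float)
    if form == "eq41":
        out = lam**2 * np.asarray(var_ybar) + zp2 * np.asarray(var_s2)
    else:
        out = lam**2 * (np.asarray(var_ybar) + zp2 * np.asarray(var_s2))
    return out if out.ndim else float(out)


def weighted_common(lambdas, variances):
    """Inverse-variance weighted average of log-scale percentiles.

    Returns ``(lambda_p, theta)`` with ``theta = exp(lambda_p)``.  Accepts
    per-group arrays of draws (combination is element-wise along the last
    axis) or plain scalars.
    """
    lam = np.asarray(lambdas, dtype=float)
    var = np.asarray(variances, dtype=float)
    if lam.shape != var.shape:
        raise ValueError("lambdas and variances must have matching shapes")
    if np.any(var <= 0):
        raise ValueError("all variances must be positive")
    w = 1.0 / var
    lam_p = np.sum(lam * w, axis=0) / np.sum(w, axis=0)
    return (float(lam_p), float(np.exp(lam_p))) if lam_p.ndim == 0 else (lam_p, np.exp(lam_p))


@dataclass(frozen=True)
class GroupPercentileEstimate:
    """Point estimate and variance pieces for one group."""

    lambda_hat: float
    var_ybar: float
    var_s2: float
    var_lambda: float

    @property
    def weight(self) -> float:
        return 1.0 / self.var_lambda


@dataclass(frozen=True)
class CommonPercentileEstimate:
    lambda_p: float
    theta: float
    per_group: tuple[GroupPercentileEstimate, ...] = field(default=())


def common_percentile_estimate(
    summaries: Sequence[GroupSummary], p: float, form: str = "eq41"
) -> CommonPercentileEstimate:
    """Point estimate of the common percentile from per-group summaries.

    Variances are the asymptotic formulas evaluated at the plug-in
    estimates (ybar1, s2_1) of each group.
    """
    per = []
    for s in summaries:
        lam = lambda_hat(s, p)
        vy = var_ybar1(s.ybar1, s.s2_1, s.n1)
        vs = var_s2_1(s.ybar1, s.s2_1, s.n1)
        per.append(
            GroupPercentileEstimate(
                lambda_hat=lam,
                var_ybar=vy,
                var_s2=vs,
                var_lambda=var_lambda(lam, vy, vs, p, form),
            )
        )
    lam_p, theta = weighted_common(
        [g.lambda_hat for g in per], [g.var_lambda for g in per]
    )
    return CommonPercentileEstimate(lambda_p=lam_p, theta=theta, per_group=tuple(per))
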