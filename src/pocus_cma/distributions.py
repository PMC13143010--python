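"""Parametric uncertainty distributions fitted from point estimates and 95% CIs.

Published health-economic model inputs are typically reported as a point
estimate with a 95% uncertainty interval and a named distribution family
(Gamma for costs, Beta for probabilities).  A two-parameter family cannot in
general match a mean *and* both interval endpoints, so two fitting
conventions coexist in practice and both are implemented here:

``quantile``
    Solve the shape parameters so the 2.5% and 97.5% quantiles equal the
    interval endpoints exactly.  The discrepancy between the fitted mean and
    the published point estimate is recorded on the fit, never discarded.
``moments``
    Anchor the mean at the point estimate and set the standard deviation to
    (ci_upper - ci_lower) / (2 * z_0.975), i.e. treat the interval as a
    normal-approximation 95% CI.  This is the conventional parameterization
    in decision-analytic software and keeps the sampled mean on the point
    estimate even for heavily skewed intervals.

Quantile matching is the default of :func:`fit_beta` / :func:`fit_gamma`;
probabilistic sensitivity analysis samples moment-matched fits by default
(see :mod:`pocus_cma.psa`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import optimize, stats

__all__ = [
    "DistributionSpec",
    "FittedDistribution",
    "FittingError",
    "fit_beta",
    "fit_gamma",
    "fit_point",
    "fit_distribution",
    "sample_distribution",
    "quantile_residuals",
]

#: two-sided 95% interval quantiles
Q_LO, Q_HI = 0.025, 0.975
#: z_0.975, the half-width of a standard-normal 95% interval
Z95 = float(stats.norm.ppf(Q_HI))

FitMethod = Literal["quantile", "moments"]


class FittingError(RuntimeError):
    """Raised when no distribution in the family can honour the inputs."""


class DistributionSpec(BaseModel):
    """One published model input: point estimate, 95% CI and family.

    ``ci_lower``/``ci_upper`` are interval *endpoints*, never shape
    parameters; a Beta(0.88, 0.93) read as shape parameters would have mean
    0.486, inconsistent with any published accuracy near 0.91.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    family: Literal["gamma", "beta", "point"]
    point_estimate: float
    ci_lower: float
    ci_upper: float
    source_label: str = ""

    @model_validator(mode="after")
    def _check_invariants(self) -> "DistributionSpec":
        lo, hi, pt = self.ci_lower, self.ci_upper, self.point_estimate
        if self.family == "point":
            if not (lo <= pt <= hi):
                raise ValueError(f"{self.name}: need ci_lower <= estimate <= ci_upper")
            return self
        if not (lo < hi):
            raise ValueError(
                f"{self.name}: degenerate interval [{lo}, {hi}]; use family='point'"
            )
        if not (lo <= pt <= hi):
            raise ValueError(f"{self.name}: point estimate {pt} outside CI [{lo}, {hi}]")
        if self.family == "beta" and not (0.0 <= lo and hi <= 1.0):
            raise ValueError(f"{self.name}: beta CI must lie in [0, 1]")
        if self.family == "gamma" and not lo > 0.0:
            raise ValueError(f"{self.name}: gamma CI lower bound must be > 0")
        return self


@dataclass(frozen=True)
class FittedDistribution:
    """A fitted parametric form for one :class:`DistributionSpec`.

    ``shape_a``/``shape_b`` are Gamma shape/rate or Beta alpha/beta; for a
    point mass both are NaN and sampling returns the constant.
    ``mean_discrepancy`` is ``fitted_mean - point_estimate`` and is reported,
    not enforced (a two-parameter family cannot match mean and two quantiles
    simultaneously).
    """

    spec: DistributionSpec
    shape_a: float
    shape_b: float
    fitted_mean: float
    mean_discrepancy: float
    method: str = "quantile"

    @property
    def family(self) -> str:
        return self.spec.family

    def ppf(self, q):
        """Quantile function of the fitted form."""
        if self.family == "gamma":
            return stats.gamma.ppf(q, self.shape_a, scale=1.0 / self.shape_b)
        if self.family == "beta":
            return stats.beta.ppf(q, self.shape_a, self.shape_b)
        return np.full_like(np.asarray(q, dtype=float), self.spec.point_estimate)

    def cdf(self, x):
        if self.family == "gamma":
            return stats.gamma.cdf(x, self.shape_a, scale=1.0 / self.shape_b)
        if self.family == "beta":
            return stats.beta.cdf(x, self.shape_a, self.shape_b)
        return (np.asarray(x, dtype=float) >= self.spec.point_estimate).astype(float)


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def fit_beta(spec: DistributionSpec, method: FitMethod = "quantile") -> FittedDistribution:
    """Fit Beta(alpha, beta) to a probability's point estimate and 95% CI.

    Quantile matching solves the two shape parameters by 2-D root finding on
    the quantile residuals.  An interval whose upper endpoint is 1.0 (printed
    precision) cannot have a proper Beta 97.5% quantile of exactly 1; in that
    case the lower quantile and the mean are matched instead, which keeps the
    fit faithful to both printed values that *are* attainable.
    """
    if spec.family != "beta":
        raise ValueError(f"{spec.name}: fit_beta requires family='beta'")
    lo, hi, pt = spec.ci_lower, spec.ci_upper, spec.point_estimate

    if method == "moments":
        sd = (min(hi, 1.0) - lo) / (2.0 * Z95)
        var = sd * sd
        if var >= pt * (1.0 - pt):
            raise FittingError(
                f"{spec.name}: CI width implies variance {var:.4g} >= m(1-m); "
                "no beta has these moments"
            )
        nu = pt * (1.0 - pt) / var - 1.0
        a, b = pt * nu, (1.0 - pt) * nu
        return FittedDistribution(spec, a, b, pt, 0.0, "moments")

    if hi >= 1.0:
        # one-sided fit: match q2.5 and the mean (see docstring)
        def resid(x):
            a, b = np.exp(x)
            return [
                stats.beta.ppf(Q_LO, a, b) - lo,
                a / (a + b) - pt,
            ]
    else:
        def resid(x):
            a, b = np.exp(x)
            return [
                stats.beta.ppf(Q_LO, a, b) - lo,
                stats.beta.ppf(Q_HI, a, b) - hi,
            ]

    # moment-based starting point from the interval itself
    m0 = min(max(pt if hi >= 1.0 else 0.5 * (lo + hi), 1e-6), 1 - 1e-6)
    sd0 = max((min(hi, 1.0) - lo) / (2.0 * Z95), 1e-6)
    nu0 = max(m0 * (1.0 - m0) / sd0**2 - 1.0, 1e-2)
    x0 = np.log([m0 * nu0, (1.0 - m0) * nu0])

    sol = optimize.root(resid, x0, method="hybr", tol=1e-12)
    if not sol.success or max(abs(r) for r in resid(sol.x)) > 1e-8:
        raise FittingError(f"{spec.name}: beta quantile fit did not converge")
    a, b = np.exp(sol.x)
    mean = a / (a + b)
    return FittedDistribution(spec, float(a), float(b), float(mean), float(mean - pt))


def _gamma_log_ratio(log_k: float) -> float:
    k = math.exp(log_k)
    q_lo = stats.gamma.ppf(Q_LO, k)
    q_hi = stats.gamma.ppf(Q_HI, k)
    if q_lo <= 0.0 or not np.isfinite(q_lo):
        return math.inf
    return math.log(q_hi) - math.log(q_lo)


def fit_gamma(spec: DistributionSpec, method: FitMethod = "quantile") -> FittedDistribution:
    """Fit Gamma(shape, rate) to a cost's point estimate and 95% CI.

    The quantile ratio q97.5/q2.5 of a Gamma is scale-free and strictly
    decreasing in the shape, so the shape is found by 1-D bracketing on
    log-shape and the rate then follows from either endpoint.
    """
    if spec.family != "gamma":
        raise ValueError(f"{spec.name}: fit_gamma requires family='gamma'")
    lo, hi, pt = spec.ci_lower, spec.ci_upper, spec.point_estimate

    if method == "moments":
        if pt <= 0:
            raise FittingError(f"{spec.name}: moment fit needs a positive point estimate")
        sd = (hi - lo) / (2.0 * Z95)
        shape = (pt / sd) ** 2
        rate = shape / pt
        return FittedDistribution(spec, float(shape), float(rate), pt, 0.0, "moments")

    target = math.log(hi) - math.log(lo)
    lk_lo, lk_hi = math.log(1e-3), math.log(1e5)
    # shrink the lower bracket end until the ratio is finite there
    while not np.isfinite(_gamma_log_ratio(lk_lo)) and lk_lo < lk_hi:
        lk_lo += 0.5
    f_lo, f_hi = _gamma_log_ratio(lk_lo) - target, _gamma_log_ratio(lk_hi) - target
    if not (f_lo > 0.0 > f_hi):
        raise FittingError(
            f"{spec.name}: CI ratio {hi / lo:.4g} outside the range achievable "
            "by a gamma shape in [1e-3, 1e5]"
        )
    log_k = optimize.brentq(
        lambda x: _gamma_log_ratio(x) - target, lk_lo, lk_hi, xtol=1e-13, rtol=1e-15
    )
    shape = math.exp(log_k)
    rate = stats.gamma.ppf(Q_LO, shape) / lo
    mean = shape / rate
    return FittedDistribution(spec, float(shape), float(rate), float(mean), float(mean - pt))


def fit_point(spec: DistributionSpec) -> FittedDistribution:
    if spec.family != "point":
        raise ValueError(f"{spec.name}: fit_point requires family='point'")
    return FittedDistribution(spec, math.nan, math.nan, spec.point_estimate, 0.0, "point")


def fit_distribution(spec: DistributionSpec, method: FitMethod = "quantile") -> FittedDistribution:
    """Dispatch on the spec's family."""
    if spec.family == "gamma":
        return fit_gamma(spec, method)
    if spec.family == "beta":
        return fit_beta(spec, method)
    return fit_point(spec)


def sample_distribution(fit: FittedDistribution, n: int, rng_seed) -> np.ndarray:
    """Draw ``n`` reproducible samples; ``rng_seed`` is an int seed or Generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng_seed)
    if fit.family == "gamma":
        return rng.gamma(fit.shape_a, 1.0 / fit.shape_b, size=n)
    if fit.family == "beta":
        return rng.beta(fit.shape_a, fit.shape_b, size=n)
    return np.full(n, fit.spec.point_estimate, dtype=float)


def quantile_residuals(fit: FittedDistribution) -> tuple[float, float]:
    """(q2.5 - ci_lower, q97.5 - ci_upper) of the fitted form."""
    return (
        float(fit.ppf(Q_LO) - fit.spec.ci_lower),
        float(fit.ppf(Q_HI) - fit.spec.ci_upper),
    )
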