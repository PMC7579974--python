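"""Confidence intervals for the between-study variance τ².

Four 95% (by default) interval methods:

* QP — Q-profile: τ² values not rejected by referring the
  inverse-variance Q statistic at τ² to χ²(K−1);
* BJ — generalized Q-profile using the exact distribution of Cochran's Q
  (fixed weights a_i = 1/v̂_i²) as a positive linear combination of
  independent χ²(1) variables;
* J  — the same construction with a_i = 1/v̂_i;
* PL — profile likelihood: τ² values not rejected by the likelihood-ratio
  test, anchored at the restricted-likelihood (REML) objective.

The BJ/J machinery needs the CDF of Σ μ_j Z_j² for independent standard
normals Z_j; :func:`weighted_chisq_cdf` computes it by Imhof-type
numerical inversion of the characteristic function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import chi2

from .dataset import MetaDataset
from .tau2 import generalized_q, q_at, reml_tau2, restricted_loglik

__all__ = [
    "Tau2Interval",
    "weighted_chisq_cdf",
    "q_profile_interval",
    "generalized_q_interval",
    "profile_likelihood_interval",
    "tau2_interval",
    "TAU2_INTERVAL_METHODS",
]

TAU2_INTERVAL_METHODS = ("QP", "BJ", "J", "PL")

#: Root tolerance for interval endpoints, in τ² units.
ROOT_TOL = 1e-10
#: Upper bracket cap; beyond it a bound is reported as open-ended (inf).
BRACKET_CAP = 1e4


@dataclass(frozen=True)
class Tau2Interval:
    """A τ² confidence interval with truncation flags.

    ``lower_truncated``/``upper_truncated`` mark bounds clipped at 0; an
    infinite ``upper`` marks an open-ended interval (root not bracketed).
    """

    method: str
    lower: float
    upper: float
    level: float = 0.95
    lower_truncated: bool = False
    upper_truncated: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if not (0.0 <= self.lower <= self.upper):
            raise ValueError(f"need 0 <= lower <= upper, got {self.lower}, {self.upper}")


def _imhof_integrand(u: float, mu: np.ndarray, x: float) -> float:
    theta = 0.5 * float(np.sum(np.arctan(mu * u))) - 0.5 * x * u
    rho = float(np.exp(0.25 * np.sum(np.log1p((mu * u) ** 2))))
    return math.sin(theta) / (u * rho)


def _imhof_cdf(mu: np.ndarray, x: float) -> float:
    """Characteristic-function inversion (Imhof's formula); fallback path."""
    integral, _ = quad(
        _imhof_integrand,
        0.0,
        np.inf,
        args=(mu, x),
        limit=1000,
        epsabs=1e-11,
        epsrel=1e-9,
    )
    return float(min(1.0, max(0.0, 0.5 - integral / math.pi)))


def _ruben_cdf(mu: np.ndarray, x: float, tol: float = 1e-9, max_terms: int = 20000):
    """Ruben's representation of P(Σ μ_j Z_j² ≤ x) as a central-χ² mixture.

    With β = min μ_j and γ_j = 1 − β/μ_j ∈ [0, 1), the distribution is a
    proper mixture Σ_k c_k χ²(m + 2k) scaled by β, with non-negative
    weights c_k summing to one, so the truncation error after N terms is
    bounded by the un-accumulated mixture mass.  Returns None if the
    series has not converged within ``max_terms`` (extreme eigenvalue
    spread); the caller then falls back to Imhof inversion.
    """
    m = mu.size
    beta = float(mu.min())
    gamma = 1.0 - beta / mu
    a0 = math.exp(0.5 * float(np.sum(np.log(beta / mu))))

    xb = x / beta
    h = np.empty(max_terms)
    g = np.empty(max_terms + 1)
    pow_gamma = np.ones_like(gamma)
    h[0] = 1.0
    total = a0  # accumulated mixture mass a0 * sum h_k
    # chi2 CDF terms via the stable downward recursion
    #   P(chi2_{df+2} <= x) = P(chi2_df <= x) - (x/2)^{df/2} e^{-x/2} / Gamma(df/2+1)
    term_f = float(chi2.cdf(xb, df=m))
    # log-space to survive the e^{-x/2} underflow at large x/beta
    log_delta = 0.5 * m * math.log(xb / 2.0) - xb / 2.0 - math.lgamma(0.5 * m + 1.0)
    cdf = a0 * term_f
    for k in range(1, max_terms):
        pow_gamma *= gamma
        g[k] = float(pow_gamma.sum())
        h[k] = 0.5 / k * float(np.dot(g[1 : k + 1], h[k - 1 :: -1]))
        term_f = max(0.0, term_f - math.exp(log_delta))
        log_delta += math.log(xb / 2.0) - math.log(0.5 * m + k)
        cdf += a0 * h[k] * term_f
        total += a0 * h[k]
        # remaining mass bounds the tail; F terms decrease in df, so the
        # tail is also below (1 - total) * current F term
        tail = (1.0 - total) * term_f
        if tail < tol:
            return min(1.0, max(0.0, cdf))
    return None


def weighted_chisq_cdf(coeffs: Sequence[float], x: float) -> float:
    """P(Σ μ_j Z_j² ≤ x) for independent standard normal Z_j.

    Coefficients must be non-negative with at least one positive;
    (relatively) negligible coefficients are dropped.  Single-coefficient
    and all-equal cases reduce to scaled χ² CDFs; otherwise Ruben's
    mixture series is summed to absolute accuracy below 1e-6, with
    Imhof characteristic-function inversion as a fallback for extreme
    eigenvalue spreads.
    """
    mu = np.asarray(coeffs, dtype=float)
    if np.any(mu < 0):
        raise ValueError("coefficients must be non-negative")
    mu = mu[mu > 0]
    if mu.size == 0:
        raise ValueError("at least one coefficient must be positive")
    if x <= 0:
        return 0.0
    # negligible coefficients perturb the CDF by O(their total mass) but
    # destroy the mixture series' convergence rate
    mu = mu[mu > 1e-9 * mu.sum()]
    if mu.size == 1 or np.allclose(mu, mu[0], rtol=1e-13, atol=0.0):
        return float(chi2.cdf(x / mu[0], df=mu.size))

    val = _ruben_cdf(mu, x)
    if val is None:
        val = _imhof_cdf(mu, x)
    return val


def _decreasing_root(f, target: float, lo: float, hi0: float) -> float:
    """Root of the strictly decreasing f(τ²) = target; inf if beyond the cap."""
    hi = hi0
    while f(hi) > target:
        hi *= 2.0
        if hi > BRACKET_CAP:
            return math.inf
    return float(brentq(lambda t: f(t) - target, lo, hi, xtol=ROOT_TOL))


def q_profile_interval(data: MetaDataset, level: float = 0.95) -> Tau2Interval:
    """Q-profile interval: solve F(τ²) = χ²(K−1) quantiles.

    F(τ²) = Σ ŵ_i(τ²)(λ̂_i − λ̂(τ²))² is strictly decreasing; the lower
    bound solves F = χ²_{1−α/2}, the upper F = χ²_{α/2}.  Bounds that do
    not exist are truncated at 0 ([0, 0] when Q is below the α/2
    quantile already at τ² = 0).
    """
    alpha = 1.0 - level
    q_hi = chi2.ppf(1 - alpha / 2, df=data.k - 1)
    q_lo = chi2.ppf(alpha / 2, df=data.k - 1)
    f = lambda t: q_at(data, t)
    q0 = f(0.0)

    if q0 <= q_lo:
        return Tau2Interval("QP", 0.0, 0.0, level, True, True)
    upper = _decreasing_root(f, q_lo, 0.0, 1.0)
    if q0 <= q_hi:
        return Tau2Interval("QP", 0.0, upper, level, lower_truncated=True)
    lower = _decreasing_root(f, q_hi, 0.0, 1.0)
    return Tau2Interval("QP", lower, upper, level)


def _bj_eigenvalues(data: MetaDataset, a: np.ndarray, tau2: float) -> np.ndarray:
    """Eigenvalues of S^{1/2} M S^{1/2}, S = diag(v̂_i²+τ²),
    M = diag(a) − a aᵀ/Σa; gives the null distribution of Q_a at τ²."""
    s_half = np.sqrt(data.var + tau2)
    m = np.diag(a) - np.outer(a, a) / np.sum(a)
    b = (s_half[:, None] * m) * s_half[None, :]
    eig = np.linalg.eigvalsh(b)
    if eig[0] < -1e-10 * max(eig[-1], 1.0):
        raise RuntimeError(f"quadratic form unexpectedly indefinite (min eig {eig[0]})")
    eig = np.clip(eig, 0.0, None)
    return eig[eig > 1e-12 * max(eig[-1], 1.0)]


def generalized_q_interval(
    data: MetaDataset, weight_rule: str = "IV-null", level: float = 0.95
) -> Tau2Interval:
    """Generalized Q-profile interval from the exact weighted-χ²
    distribution of Q_a (BJ with a_i = 1/v̂_i², J with a_i = 1/v̂_i).

    For candidate τ² the null distribution of the observed Q_a is
    Σ μ_j(τ²) χ²(1) with μ_j the eigenvalues of the quadratic-form
    matrix; P(Q_a ≤ Q_a^obs | τ²) is decreasing in τ², and the bounds
    are where it crosses 1 − α/2 and α/2.
    """
    if weight_rule == "IV-null":
        a = 1.0 / data.var
        method = "BJ"
    elif weight_rule == "inverse-SD":
        a = 1.0 / np.sqrt(data.var)
        method = "J"
    else:
        raise ValueError(f"unknown weight rule {weight_rule!r}")

    q_obs = generalized_q(data, a)
    cdf = lambda t: weighted_chisq_cdf(_bj_eigenvalues(data, a, t), q_obs)
    alpha = 1.0 - level
    p0 = cdf(0.0)

    if p0 <= alpha / 2:
        return Tau2Interval(method, 0.0, 0.0, level, True, True)
    upper = _decreasing_root(cdf, alpha / 2, 0.0, 1.0)
    if p0 <= 1 - alpha / 2:
        return Tau2Interval(method, 0.0, upper, level, lower_truncated=True)
    lower = _decreasing_root(cdf, 1 - alpha / 2, 0.0, 1.0)
    return Tau2Interval(method, lower, upper, level)


def profile_likelihood_interval(data: MetaDataset, level: float = 0.95) -> Tau2Interval:
    """Profile-likelihood interval anchored at the REML objective:
    {τ²: 2[l_R(τ̂²_REML) − l_R(τ²)] ≤ χ²(1) quantile}."""
    fit = reml_tau2(data)
    l_max = restricted_loglik(data, fit.tau2)
    crit = 0.5 * chi2.ppf(level, df=1)
    drop = lambda t: l_max - restricted_loglik(data, t)

    if drop(0.0) <= crit:
        lower, lower_trunc = 0.0, True
    else:
        lower = float(
            brentq(lambda t: drop(t) - crit, 0.0, fit.tau2, xtol=ROOT_TOL)
        )
        lower_trunc = False

    hi = max(2.0 * fit.tau2, 1.0)
    while drop(hi) < crit:
        hi *= 2.0
        if hi > BRACKET_CAP:
            warnings.warn(
                "profile likelihood is too flat to bound tau2 above; "
                "reporting an open-ended interval"
            )
            return Tau2Interval("PL", lower, math.inf, level, lower_trunc, False)
    upper = float(brentq(lambda t: drop(t) - crit, fit.tau2, hi, xtol=ROOT_TOL))
    return Tau2Interval("PL", lower, upper, level, lower_trunc, False)


def tau2_interval(data: MetaDataset, method: str, level: float = 0.95) -> Tau2Interval:
    """Dispatch on the method label: "QP", "BJ", "J" or "PL"."""
    if method == "QP":
        return q_profile_interval(data, level)
    if method == "BJ":
        return generalized_q_interval(data, "IV-null", level)
    if method == "J":
        return generalized_q_interval(data, "inverse-SD", level)
    if method == "PL":
        return profile_likelihood_interval(data, level)
    raise ValueError(
        f"unknown interval method {method!r}; expected one of {TAU2_INTERVAL_METHODS}"
    )
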