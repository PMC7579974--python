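"""Point estimation of the between-study variance τ².

Four estimators, all standard in random-effects meta-analysis:

* DL   — DerSimonian–Laird moment estimator, the a_i = 1/v̂_i² case of the
         DerSimonian–Kacker generalized moment estimator;
* J    — Jackson's generalized moment estimator with a_i = 1/v̂_i,
         intended for settings where heterogeneity is anticipated;
* MP   — Mandel–Paule: τ̂² solves Q(τ²) = K − 1 where Q(τ²) uses
         inverse-variance weights at that τ²;
* REML — maximizer of the restricted (residual) log-likelihood.

The generalized moment estimator matches the observed generalized Q
statistic with fixed weights a_i to its expectation under the
random-effects model:

    E[Q_a] = Σ a_i (v_i² + τ²) − Σ a_i² (v_i² + τ²) / Σ a_i

giving τ̂² = max(0, (Q_a − c1) / c2) with
c1 = Σ a_i v̂_i² − Σ a_i² v̂_i² / Σ a_i and c2 = Σ a_i − Σ a_i² / Σ a_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dataset import MetaDataset

__all__ = [
    "Tau2Fit",
    "generalized_q",
    "moment_tau2",
    "mandel_paule_tau2",
    "reml_tau2",
    "estimate_tau2",
    "TAU2_METHODS",
]

TAU2_METHODS = ("DL", "J", "MP", "REML")

#: Bisection/root tolerance for MP in τ² units.
MP_TOL = 1e-10
#: REML convergence tolerance in τ² units.
REML_TOL = 1e-10


@dataclass(frozen=True)
class Tau2Fit:
    """A τ² point estimate with method label and convergence diagnostics."""

    method: str
    tau2: float
    converged: bool = True
    truncated: bool = False
    iterations: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.truncated and self.tau2 != 0.0:
            raise ValueError("a truncated estimate must equal 0")


def generalized_q(data: MetaDataset, weights: Sequence[float] | None = None) -> float:
    """Generalized Cochran Q with arbitrary fixed positive weights.

    Q_a = Σ a_i (λ̂_i − λ̄_a)² with λ̄_a the a-weighted mean.  ``weights``
    defaults to the inverse-variance weights 1/v̂_i², which gives
    Cochran's Q.
    """
    y = data.lrr
    a = 1.0 / data.var if weights is None else np.asarray(weights, dtype=float)
    if a.shape != y.shape:
        raise ValueError(f"expected {y.size} weights, got {a.size}")
    if np.any(a <= 0):
        raise ValueError("weights must be strictly positive")
    ybar = np.sum(a * y) / np.sum(a)
    return float(np.sum(a * (y - ybar) ** 2))


def _weights_for_rule(data: MetaDataset, weight_rule: str) -> np.ndarray:
    if weight_rule == "IV-null":
        return 1.0 / data.var
    if weight_rule == "inverse-SD":
        return 1.0 / np.sqrt(data.var)
    raise ValueError(f"unknown weight rule {weight_rule!r}")


def moment_tau2(data: MetaDataset, weight_rule: str = "IV-null") -> Tau2Fit:
    """Generalized moment estimator of τ² with fixed weights.

    ``weight_rule="IV-null"`` (a_i = 1/v̂_i²) is the DerSimonian–Laird
    estimator; ``"inverse-SD"`` (a_i = 1/v̂_i) is Jackson's estimator.
    """
    a = _weights_for_rule(data, weight_rule)
    v = data.var
    q = generalized_q(data, a)
    sa = np.sum(a)
    c1 = float(np.sum(a * v) - np.sum(a**2 * v) / sa)
    c2 = float(sa - np.sum(a**2) / sa)
    if c2 <= 0:
        raise ValueError("degenerate weights: effectively all weight on one study")
    raw = (q - c1) / c2
    method = "DL" if weight_rule == "IV-null" else "J"
    return Tau2Fit(method=method, tau2=max(0.0, raw), truncated=raw < 0)


def q_at(data: MetaDataset, tau2: float) -> float:
    """Q statistic with inverse-variance weights evaluated at τ²:
    F(τ²) = Σ ŵ_i(τ²)(λ̂_i − λ̂(τ²))², strictly decreasing in τ².
    """
    w = 1.0 / (data.var + tau2)
    y = data.lrr
    ybar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - ybar) ** 2))


def mandel_paule_tau2(data: MetaDataset, tol: float = MP_TOL) -> Tau2Fit:
    """Mandel–Paule estimator: the root of F(τ²) = K − 1.

    F is strictly decreasing, so the root is unique; if F(0) < K − 1 the
    estimate is truncated to zero.  The root is bracketed by doubling the
    upper endpoint from 1 and found by Brent's method.
    """
    target = data.k - 1
    if q_at(data, 0.0) <= target:
        return Tau2Fit(method="MP", tau2=0.0, truncated=True)
    hi = 1.0
    expansions = 0
    while q_at(data, hi) >= target:
        hi *= 2.0
        expansions += 1
        if expansions > 200:
            raise RuntimeError(
                f"Mandel-Paule bracket expansion failed: F({hi}) still >= K-1"
            )
    root = brentq(lambda t: q_at(data, t) - target, 0.0, hi, xtol=tol)
    return Tau2Fit(method="MP", tau2=float(root), iterations=expansions)


def restricted_loglik(data: MetaDataset, tau2: float) -> float:
    """Profile restricted log-likelihood of τ² (λ profiled out, constants dropped):

    l_R(τ²) = −½[Σ log(v̂_i²+τ²) + log Σŵ_i(τ²) + Σŵ_i(τ²)(λ̂_i − λ̂(τ²))²]
    """
    w = 1.0 / (data.var + tau2)
    y = data.lrr
    ybar = np.sum(w * y) / np.sum(w)
    return float(
        -0.5
        * (
            np.sum(np.log(data.var + tau2))
            + np.log(np.sum(w))
            + np.sum(w * (y - ybar) ** 2)
        )
    )


def _tau2_upper_bound(data: MetaDataset) -> float:
    s2 = float(np.var(data.lrr, ddof=1))
    return max(10.0, 100.0 * s2)


def reml_tau2(data: MetaDataset, tol: float = REML_TOL) -> Tau2Fit:
    """REML estimator: bounded maximization of the profile restricted
    log-likelihood on [0, τ²_max] with τ²_max = max(10, 100·S²_λ̂)."""
    hi = _tau2_upper_bound(data)
    res = minimize_scalar(
        lambda t: -restricted_loglik(data, t),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(f"REML optimizer failed: {res.message}")
    tau2 = float(res.x)
    # bounded Brent never lands exactly on an endpoint; snap near-zero
    # solutions and reject near-boundary ones.
    if tau2 > hi - max(10 * tol, 1e-6 * hi) and restricted_loglik(
        data, hi
    ) > restricted_loglik(data, 0.0):
        raise RuntimeError(
            f"REML solution at the upper bound {hi}; increase tau2 search range"
        )
    truncated = False
    if tau2 < 10 * tol and restricted_loglik(data, 0.0) >= restricted_loglik(data, tau2):
        tau2, truncated = 0.0, True
    return Tau2Fit(
        method="REML",
        tau2=tau2,
        converged=bool(res.success),
        truncated=truncated,
        iterations=int(res.nit),
    )


def estimate_tau2(data: MetaDataset, method: str) -> Tau2Fit:
    """Dispatch on the method label: "DL", "J", "MP" or "REML"."""
    if method == "DL":
        return moment_tau2(data, "IV-null")
    if method == "J":
        return moment_tau2(data, "inverse-SD")
    if method == "MP":
        return mandel_paule_tau2(data)
    if method == "REML":
        return reml_tau2(data)
    raise ValueError(f"unknown tau2 method {method!r}; expected one of {TAU2_METHODS}")
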