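"""Point and interval estimation of the overall log response ratio λ.

Point estimators
----------------
* FE / RE inverse-variance means: λ̂ = Σŵ_i λ̂_i / Σŵ_i with
  ŵ_i(τ̂²) = (v̂_i² + τ̂²)⁻¹ (FE is the τ² = 0 case);
* SSW: weights are the effective sample sizes ñ_i = n_T n_C/(n_T + n_C),
  avoiding estimated-variance weights altogether.

Interval estimators
-------------------
* Wald: λ̂ ± z·(Σŵ_i)^{-1/2};
* HKSJ: λ̂_RE ± t_{K−1}·√q with the weighted residual variance
  q = Σŵ_i(λ̂_i − λ̂_RE)² / [(K−1)Σŵ_i]; the variance is used
  unmodified (no truncation at the inverse-variance value);
* SSW companion interval: λ̂_SSW ± t_{K−1}·√[Σñ_i²(v̂_i²+τ̂²_MP)/(Σñ_i)²].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm, t as t_dist

from .dataset import MetaDataset
from .tau2 import mandel_paule_tau2

__all__ = [
    "OverallFit",
    "iv_weighted_mean",
    "ssw_mean",
    "wald_interval",
    "hksj_interval",
    "ssw_interval",
    "i_squared",
]


@dataclass(frozen=True)
class OverallFit:
    """An overall-effect estimate, its SE and (optionally) a CI."""

    method: str
    estimate: float
    se: float | None = None
    lower: float | None = None
    upper: float | None = None
    level: float = 0.95
    df_rule: str = "normal"  # "normal" or "t(K-1)"
    tau2_method: str | None = None

    def __post_init__(self) -> None:
        if self.se is not None and not (self.se >= 0):
            raise ValueError("se must be >= 0")
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.estimate <= self.upper):
                raise ValueError("interval must contain its center")


def iv_weighted_mean(
    data: MetaDataset, tau2: float = 0.0, tau2_method: str | None = None
) -> OverallFit:
    """Inverse-variance weighted mean at a given τ² plug-in.

    ``tau2 = 0`` gives the fixed-effect estimate.  The SE is the
    customary (Σŵ_i)^{-1/2}.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    w = 1.0 / (data.var + tau2)
    est = float(np.sum(w * data.lrr) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    method = "FE" if tau2 == 0 and tau2_method is None else f"RE({tau2_method or 'fixed'})"
    return OverallFit(method=method, estimate=est, se=se, tau2_method=tau2_method)


def ssw_mean(data: MetaDataset) -> OverallFit:
    """Sample-size weighted mean λ̂_SSW = Σñ_i λ̂_i / Σñ_i."""
    n_eff = data.effective_n  # raises if arm sizes are unavailable
    est = float(np.sum(n_eff * data.lrr) / np.sum(n_eff))
    return OverallFit(method="SSW", estimate=est)


def wald_interval(fit: OverallFit, level: float = 0.95) -> OverallFit:
    """Normal-theory interval λ̂ ± z_{1−α/2}·se around an existing fit."""
    if fit.se is None:
        raise ValueError("fit has no standard error")
    z = norm.ppf(0.5 + level / 2)
    return replace(
        fit,
        lower=fit.estimate - z * fit.se,
        upper=fit.estimate + z * fit.se,
        level=level,
        df_rule="normal",
    )


def hksj_interval(
    data: MetaDataset,
    tau2: float,
    level: float = 0.95,
    tau2_method: str | None = None,
) -> OverallFit:
    """Hartung–Knapp–Sidik–Jonkman interval around the IV-weighted mean.

    Uses the weighted residual variance
    q = Σŵ_i(τ̂²)(λ̂_i − λ̂_RE)² / [(K−1)·Σŵ_i(τ̂²)] and t(K−1) critical
    values.  Plugging in the Mandel–Paule τ̂² gives the HKSJ-MP variant.
    """
    if data.k < 2:
        raise ValueError("HKSJ requires K >= 2 (no degrees of freedom otherwise)")
    w = 1.0 / (data.var + tau2)
    center = float(np.sum(w * data.lrr) / np.sum(w))
    q = float(np.sum(w * (data.lrr - center) ** 2) / ((data.k - 1) * np.sum(w)))
    half = t_dist.ppf(0.5 + level / 2, df=data.k - 1) * math.sqrt(q)
    return OverallFit(
        method=f"HKSJ({tau2_method})" if tau2_method else "HKSJ",
        estimate=center,
        se=math.sqrt(q),
        lower=center - half,
        upper=center + half,
        level=level,
        df_rule="t(K-1)",
        tau2_method=tau2_method,
    )


def ssw_interval(
    data: MetaDataset, level: float = 0.95, tau2: float | None = None
) -> OverallFit:
    """t(K−1) interval around λ̂_SSW with
    Var̂(λ̂_SSW) = Σñ_i²(v̂_i² + τ̂²)/(Σñ_i)², τ̂² the Mandel–Paule
    estimate unless supplied."""
    if tau2 is None:
        tau2 = mandel_paule_tau2(data).tau2
    n_eff = data.effective_n
    center = float(np.sum(n_eff * data.lrr) / np.sum(n_eff))
    var = float(np.sum(n_eff**2 * (data.var + tau2)) / np.sum(n_eff) ** 2)
    half = t_dist.ppf(0.5 + level / 2, df=data.k - 1) * math.sqrt(var)
    return OverallFit(
        method="SSW MP",
        estimate=center,
        se=math.sqrt(var),
        lower=center - half,
        upper=center + half,
        level=level,
        df_rule="t(K-1)",
        tau2_method="MP",
    )


def i_squared(tau2: float, data: MetaDataset) -> float:
    """I² = 100·τ²/(τ² + s²) with s² the Higgins–Thompson typical
    within-study variance s² = (K−1)Σŵ_i / [(Σŵ_i)² − Σŵ_i²],
    ŵ_i = 1/v̂_i².  Returned as a percentage in [0, 100)."""
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    w = 1.0 / data.var
    s2 = (data.k - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
    return float(100.0 * tau2 / (tau2 + s2))
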