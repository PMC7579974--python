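"""Study-level estimation of the log response ratio (LRR).

A two-arm study reports, for each arm, a sample size, a sample mean and a
sample standard deviation.  The effect measure is the log of the ratio of
arm means, ``lrr = log(mean_T / mean_C)``, with a delta-method within-study
variance equal to the sum of the squared sample coefficients of variation
divided by the arm sample sizes:

    var = s_T^2 / (n_T * mean_T^2) + s_C^2 / (n_C * mean_C^2)

The LRR is undefined when either sample mean is non-positive; under a
normal data model this happens with positive probability, quantified by
:func:`prob_undefined`.  A second-order bias correction (recommended for
lognormal data, harmful for normal data) adjusts both the point estimate
and its variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "ArmSummary",
    "PopulationArm",
    "StudyEffect",
    "UndefinedLRRError",
    "DegenerateVarianceError",
    "compute_lrr",
    "precision_flag",
    "prob_undefined",
]

#: √n·mean/sd threshold below which the normal approximation to the LRR
#: is considered unreliable for an arm.
PRECISION_THRESHOLD = 3.0


class UndefinedLRRError(ValueError):
    """Raised when a non-positive sample mean makes the LRR undefined.

    Attributes
    ----------
    arm : str
        Which arm ("treatment" or "control") has the offending mean.
    """

    def __init__(self, arm: str, mean: float):
        self.arm = arm
        self.mean = mean
        super().__init__(
            f"LRR undefined: {arm} arm has non-positive sample mean {mean!r}"
        )


class DegenerateVarianceError(ValueError):
    """Raised when both arms have zero variance (no sampling noise to model)."""


@dataclass(frozen=True)
class ArmSummary:
    """Sufficient statistics (n, mean, sd) for one arm of a study."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"arm sample size must be >= 2, got {self.n}")
        if not math.isfinite(self.mean):
            raise ValueError("arm mean must be finite")
        if not (self.sd >= 0):
            raise ValueError(f"arm sd must be >= 0, got {self.sd}")

    @property
    def cv(self) -> float:
        """Sample coefficient of variation sd/mean (computed, never stored)."""
        return self.sd / self.mean


@dataclass(frozen=True)
class PopulationArm:
    """Population-level description of one arm: mean, SD and planned n."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"population sigma must be > 0, got {self.sigma}")
        if self.n < 2:
            raise ValueError(f"planned sample size must be >= 2, got {self.n}")


@dataclass(frozen=True)
class StudyEffect:
    """A study's LRR estimate and its estimated within-study variance."""

    lrr: float
    var: float
    bias_corrected: bool = False
    precision_ok: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.lrr):
            raise ValueError("lrr must be finite")
        if not (self.var > 0):
            raise ValueError(f"within-study variance must be > 0, got {self.var}")


def compute_lrr(
    treatment: ArmSummary, control: ArmSummary, bias_correct: bool = False
) -> StudyEffect:
    """Estimate a study's LRR and within-study variance from arm summaries.

    Parameters
    ----------
    treatment, control
        Arm-level sufficient statistics.  Both sample means must be
        strictly positive.
    bias_correct
        Apply the second-order (Lajeunesse) correction to the point
        estimate and its variance.  Recommended for lognormal data only.

    Returns
    -------
    StudyEffect
        With ``precision_ok`` True when at least one arm satisfies
        √n·mean/sd ≥ 3.

    Raises
    ------
    UndefinedLRRError
        If either arm has a non-positive sample mean.
    DegenerateVarianceError
        If both arms have zero sample SD.
    """
    if treatment.mean <= 0:
        raise UndefinedLRRError("treatment", treatment.mean)
    if control.mean <= 0:
        raise UndefinedLRRError("control", control.mean)
    if treatment.sd == 0 and control.sd == 0:
        raise DegenerateVarianceError(
            "both arms report zero SD; the within-study variance is zero"
        )

    gt = treatment.sd**2 / (treatment.n * treatment.mean**2)
    gc = control.sd**2 / (control.n * control.mean**2)

    lrr = math.log(treatment.mean / control.mean)
    var = gt + gc
    if bias_correct:
        lrr += 0.5 * (gt - gc)
        var += 0.5 * (gt**2 - gc**2)
    if var <= 0:
        raise DegenerateVarianceError(
            f"bias-corrected variance is non-positive ({var!r})"
        )

    ok = precision_flag(treatment) or precision_flag(control)
    return StudyEffect(lrr=lrr, var=var, bias_corrected=bias_correct, precision_ok=ok)


def precision_flag(arm: ArmSummary) -> bool:
    """True when √n·mean/sd ≥ 3, i.e. the arm mean is far enough from zero.

    The flag is advisory only: studies failing it are reported, never
    dropped automatically (the rule is widely ignored in practice).  A zero
    SD gives an infinite ratio; the flag is True with a warning.
    """
    if arm.sd == 0:
        warnings.warn(
            "arm has zero SD; precision ratio is infinite", stacklevel=2
        )
        return True
    return math.sqrt(arm.n) * arm.mean / arm.sd >= PRECISION_THRESHOLD


def prob_undefined(treatment: PopulationArm, control: PopulationArm) -> float:
    """Probability that the LRR is undefined under normal arm means.

    With X̄_j ~ N(mu_j, sigma_j^2/n_j) the LRR is undefined when either
    sample mean is non-positive:

        1 - [1 - Φ(-√n_C·mu_C/sigma_C)] [1 - Φ(-√n_T·mu_T/sigma_T)]

    Decreasing in each n_j and each mu_j/sigma_j ratio.
    """
    a_c = math.sqrt(control.n) * control.mu / control.sigma
    a_t = math.sqrt(treatment.n) * treatment.mu / treatment.sigma
    return float(1.0 - (1.0 - norm.cdf(-a_c)) * (1.0 - norm.cdf(-a_t)))
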