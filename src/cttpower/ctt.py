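"""Classical test theory variance algebra.

Classical test theory (CTT) decomposes an observed score X into an
unobserved true score T and a random error score E, X = T + E, with T and
E uncorrelated.  At the population level this gives

    sigma_X^2 = sigma_T^2 + sigma_E^2
    rho_XX'   = sigma_T^2 / sigma_X^2

where ``rho_XX'`` (reliability) is the proportion of observed-score
variance attributable to real individual differences.  Everything in this
module is exact algebra on these three variances; no data are involved.

Variances are stored as variances throughout, never standard deviations;
use :func:`sd_to_var` / :func:`var_to_sd` at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "VarianceComponents",
    "reliability_from_components",
    "error_variance_fixed_true",
    "true_variance_fixed_error",
    "decompose_observed",
    "spearman_brown",
    "sd_to_var",
    "var_to_sd",
    "display_round",
]

_TOL = 1e-12


@dataclass(frozen=True)
class VarianceComponents:
    """Population variance decomposition of one group's observed scores.

    Parameters are population quantities, so ``rho`` must lie in [0, 1]
    exactly; sample *estimates* of reliability (which can stray slightly
    outside the unit interval) belong in estimate containers such as
    :class:`cttpower.reliability.SplitHalfResult`, not here.
    """

    sigma_T2: float
    sigma_E2: float

    def __post_init__(self) -> None:
        if self.sigma_T2 < 0 or self.sigma_E2 < 0:
            raise ValueError(
                f"variances must be non-negative, got sigma_T2={self.sigma_T2}, "
                f"sigma_E2={self.sigma_E2}"
            )

    @property
    def sigma_X2(self) -> float:
        return self.sigma_T2 + self.sigma_E2

    @property
    def rho(self) -> float:
        if self.sigma_X2 <= 0:
            raise ValueError("reliability undefined: total variance is zero")
        return self.sigma_T2 / self.sigma_X2

    def as_dict(self, *, display: bool = False) -> dict[str, float]:
        d = {
            "sigma_T2": self.sigma_T2,
            "sigma_E2": self.sigma_E2,
            "sigma_X2": self.sigma_X2,
            "rho": self.rho,
        }
        if display:
            d = {k: display_round(v) for k, v in d.items()}
        return d


def reliability_from_components(sigma_T2: float, sigma_E2: float) -> float:
    """Reliability as the ratio of true-score to observed-score variance.

    rho = sigma_T^2 / (sigma_T^2 + sigma_E^2).
    """
    if sigma_T2 < 0 or sigma_E2 < 0:
        raise ValueError("variances must be non-negative")
    total = sigma_T2 + sigma_E2
    if total <= 0:
        raise ValueError("reliability undefined when both variances are zero")
    return sigma_T2 / total


def error_variance_fixed_true(rho: float, sigma_T2: float = 1.0) -> float:
    """Error variance implied by reliability when true-score variance is held fixed.

    Solving rho = sigma_T^2 / (sigma_T^2 + sigma_E^2) for sigma_E^2 gives
    sigma_E^2 = sigma_T^2 * (1 - rho) / rho.  Strictly decreasing in rho;
    diverges as rho -> 0.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1] for fixed true-score variance, got {rho}")
    if sigma_T2 < 0:
        raise ValueError("sigma_T2 must be non-negative")
    return sigma_T2 * (1.0 - rho) / rho


def true_variance_fixed_error(rho: float, sigma_E2: float = 1.0) -> float:
    """True-score variance implied by reliability when error variance is held fixed.

    sigma_T^2 = sigma_E^2 * rho / (1 - rho); the implied observed variance is
    sigma_E^2 / (1 - rho).  Strictly increasing in rho; diverges as rho -> 1.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1) for fixed error-score variance, got {rho}")
    if sigma_E2 < 0:
        raise ValueError("sigma_E2 must be non-negative")
    return sigma_E2 * rho / (1.0 - rho)


def decompose_observed(sigma_X2: float, rho: float) -> VarianceComponents:
    """Split an observed variance into true and error components at reliability rho.

    sigma_T^2 = rho * sigma_X^2 and sigma_E^2 = sigma_X^2 - rho * sigma_X^2.
    Round-trips through :func:`reliability_from_components` to within 1e-12.
    """
    if sigma_X2 < 0:
        raise ValueError("sigma_X2 must be non-negative")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    sigma_T2 = rho * sigma_X2
    return VarianceComponents(sigma_T2=sigma_T2, sigma_E2=sigma_X2 - sigma_T2)


def spearman_brown(r: float) -> float:
    """Project a half-test correlation to full-test reliability: 2r / (1 + r).

    Negative inputs pass through (the result is then negative and should be
    interpreted as an estimate, not a population reliability).
    """
    if not -1.0 < r <= 1.0:
        raise ValueError(f"half-test correlation must be in (-1, 1], got {r}")
    return 2.0 * r / (1.0 + r)


def sd_to_var(sd: float) -> float:
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    return sd * sd


def var_to_sd(var: float) -> float:
    if var < 0:
        raise ValueError("variance must be non-negative")
    return math.sqrt(var)


def display_round(x: float, ndigits: int = 3) -> float:
    """Round half away from zero for report display (0.0215 -> 0.022).

    Python's built-in ``round`` is banker's rounding; group reports use the
    half-away-from-zero convention common in print. Raw values are always
    kept unrounded — this touches display fields only.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
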