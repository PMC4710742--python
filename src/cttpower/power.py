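"""Exact power of a two-group mean comparison as a function of reliability.

For a smallest relevant difference delta > 0, per-condition sample size N,
significance level alpha and within-group observed-score SD sigma, power is

    pi(delta) = 1 - F_{df, ncp}(t_crit)

where F is the CDF of the noncentral t-distribution and t_crit the upper
critical value of the central t with the same df.  Two degrees-of-freedom
conventions are supported:

``formula="paper"``
    df = N - 1, ncp = sqrt(N) * delta / sigma — a one-sample/paired layout.
``formula="standard_two_sample"``
    df = 2(N - 1), ncp = sqrt(N / 2) * delta / sigma — the usual equal-n,
    equal-variance two-sample t-test.

Both variants produce the same qualitative reliability-power relationships.

The reliability-power paradox is made concrete by two calibration scenarios
for sigma:

``fixed_true``
    sigma_T^2 = 1 and sigma_E^2 = (1 - rho) / rho, so sigma^2 = 1/rho:
    higher reliability means less total noise and power *increases* in rho.
``fixed_error``
    sigma_E^2 = 1 and sigma_T^2 = rho / (1 - rho), so sigma^2 = 1/(1 - rho):
    higher reliability means more between-person spread and power
    *decreases* in rho.

Neither scenario is more correct; together they show there is no fixed
relation between reliability and power.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ctt import error_variance_fixed_true, true_variance_fixed_error

__all__ = [
    "PowerSpec",
    "PowerSurface",
    "exact_power",
    "power_surface",
    "scenario_sigma2",
    "FIGURE_RHO_FIXED_TRUE",
    "FIGURE_RHO_FIXED_ERROR",
    "FIGURE_N_GRID",
]

# Grids used for the two reference power surfaces.
FIGURE_RHO_FIXED_TRUE: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))
FIGURE_RHO_FIXED_ERROR: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(0, 10))
FIGURE_N_GRID: tuple[int, ...] = (10, 20, 30, 40, 50)

_TAILS = ("one_sided", "two_sided")
_FORMULAS = ("paper", "standard_two_sample")
_SCENARIOS = ("fixed_true", "fixed_error")


@dataclass(frozen=True)
class PowerSpec:
    """Parameters of one exact power evaluation.

    N is the number of observations per condition; delta the smallest
    relevant mean difference (score units); sigma the within-group
    observed-score SD.  ``tails`` defaults to one-sided, matching the single
    critical value in the power expression above.
    """

    N: int
    delta: float
    alpha: float = 0.05
    sigma: float = 1.0
    tails: str = "one_sided"
    formula: str = "paper"

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N}")
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tails not in _TAILS:
            raise ValueError(f"tails must be one of {_TAILS}, got {self.tails!r}")
        if self.formula not in _FORMULAS:
            raise ValueError(f"formula must be one of {_FORMULAS}, got {self.formula!r}")

    @property
    def df(self) -> float:
        return self.N - 1 if self.formula == "paper" else 2 * (self.N - 1)

    @property
    def ncp(self) -> float:
        scale = math.sqrt(self.N) if self.formula == "paper" else math.sqrt(self.N / 2.0)
        return scale * self.delta / self.sigma

    @property
    def t_crit(self) -> float:
        tail_alpha = self.alpha if self.tails == "one_sided" else self.alpha / 2.0
        return float(stats.t.ppf(1.0 - tail_alpha, self.df))


def exact_power(spec: PowerSpec) -> float:
    """Exact power from the noncentral t-distribution.

    One-sided: P(T > t_crit) with T ~ noncentral t(df, ncp).  Two-sided adds
    the lower rejection region P(T < -t_crit), so the value equals the
    rejection probability of the corresponding two-sided t-test (the lower
    tail is vanishingly small for the positive noncentralities of interest).
    """
    upper = float(stats.nct.sf(spec.t_crit, spec.df, spec.ncp))
    if spec.tails == "two_sided":
        lower = float(stats.nct.cdf(-spec.t_crit, spec.df, spec.ncp))
        # scipy's noncentral-t CDF can underflow to NaN deep in the far
        # tail at large ncp; the true mass there is below Phi(-ncp) ~ 0
        if math.isfinite(lower):
            upper += lower
    return min(max(upper, 0.0), 1.0)


def scenario_sigma2(scenario: str, rho: float) -> float:
    """Observed-score variance implied by reliability under a calibration scenario."""
    if scenario == "fixed_true":
        if not 0.0 < rho <= 1.0:
            raise ValueError(
                f"fixed_true requires rho in (0, 1]; rho={rho} is outside the domain"
            )
        return 1.0 + error_variance_fixed_true(rho, sigma_T2=1.0)
    if scenario == "fixed_error":
        if not 0.0 <= rho < 1.0:
            raise ValueError(
                f"fixed_error requires rho in [0, 1); rho={rho} is outside the domain"
            )
        return true_variance_fixed_error(rho, sigma_E2=1.0) + 1.0
    raise ValueError(f"scenario must be one of {_SCENARIOS}, got {scenario!r}")


@dataclass(frozen=True)
class PowerSurface:
    """Exact power over a reliability x sample-size grid for one scenario.

    ``power[i, j]`` is the power at ``rho_grid[i]``, ``N_grid[j]``.
    """

    scenario: str
    rho_grid: tuple[float, ...]
    N_grid: tuple[int, ...]
    delta: float
    alpha: float
    tails: str
    formula: str
    power: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.rho_grid), len(self.N_grid)):
            raise ValueError("power matrix shape does not match grids")
        if np.any((self.power < 0) | (self.power > 1)):
            raise ValueError("power values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": self.scenario,
                "rho": rho,
                "N": n,
                "delta": self.delta,
                "alpha": self.alpha,
                "tails": self.tails,
                "formula": self.formula,
                "power": self.power[i, j],
            }
            for i, rho in enumerate(self.rho_grid)
            for j, n in enumerate(self.N_grid)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "scenario": self.scenario,
            "rho_grid": list(self.rho_grid),
            "N_grid": [int(n) for n in self.N_grid],
            "delta": self.delta,
            "alpha": self.alpha,
            "tails": self.tails,
            "formula": self.formula,
            "power": self.power.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def power_surface(
    scenario: str,
    rho_grid: Sequence[float] | None = None,
    N_grid: Sequence[int] | None = None,
    delta: float = 0.5,
    alpha: float = 0.05,
    tails: str = "one_sided",
    formula: str = "paper",
) -> PowerSurface:
    """Evaluate exact power over a rho x N grid under one calibration scenario.

    Defaults reproduce the reference grids: rho in {0.1, ..., 1.0} for
    ``fixed_true`` or {0.0, ..., 0.9} for ``fixed_error``, N in {10, ..., 50},
    alpha = 0.05, delta = 0.5.
    """
    if rho_grid is None:
        rho_grid = FIGURE_RHO_FIXED_TRUE if scenario == "fixed_true" else FIGURE_RHO_FIXED_ERROR
    if N_grid is None:
        N_grid = FIGURE_N_GRID
    rho_grid = tuple(float(r) for r in rho_grid)
    N_grid = tuple(int(n) for n in N_grid)
    if not rho_grid or not N_grid:
        raise ValueError("rho_grid and N_grid must be non-empty")

    power = np.empty((len(rho_grid), len(N_grid)))
    for i, rho in enumerate(rho_grid):
        sigma = math.sqrt(scenario_sigma2(scenario, rho))
        for j, n in enumerate(N_grid):
            power[i, j] = exact_power(
                PowerSpec(N=n, delta=delta, alpha=alpha, sigma=sigma, tails=tails, formula=formula)
            )
    return PowerSurface(
        scenario=scenario,
        rho_grid=rho_grid,
        N_grid=N_grid,
        delta=delta,
        alpha=alpha,
        tails=tails,
        formula=formula,
        power=power,
    )
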