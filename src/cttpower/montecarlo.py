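"""Monte Carlo replication-probability simulator.

Treats the probability of replicating a significant effect as a case of
statistical power and estimates it by simulating many experiments under the
CTT generating model: each observed score is a true-score draw plus an
independent error draw, with variances set by the calibration scenario
(fixed true-score variance vs fixed error-score variance).

This is the stochastic oracle for :func:`cttpower.power.exact_power`: the
simulated test statistic matches the chosen formula variant, so the observed
rejection fraction must agree with the exact value up to binomial noise.
``formula="paper"`` simulates the corresponding one-sample layout (N scores
with mean delta, t-test against zero on N-1 df); ``standard_two_sample``
simulates two independent groups of N differing by delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ctt import decompose_observed
from .power import PowerSpec, scenario_sigma2

__all__ = ["MCConfig", "MCResult", "mc_power"]


@dataclass(frozen=True)
class MCConfig:
    spec: PowerSpec
    scenario: str
    rho: float
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        scenario_sigma2(self.scenario, self.rho)  # domain check

    @property
    def sigma_X2(self) -> float:
        return scenario_sigma2(self.scenario, self.rho)


@dataclass(frozen=True)
class MCResult:
    p_sig: float
    reps: int
    mc_se: float
    seed: int

    def as_dict(self) -> dict:
        return {"p_sig": self.p_sig, "reps": self.reps, "mc_se": self.mc_se, "seed": self.seed}


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    m = x.mean(axis=1)
    s = x.std(axis=1, ddof=1)
    return m / (s / math.sqrt(n))


def mc_power(config: MCConfig, delta: float | None = None) -> MCResult:
    """Fraction of simulated experiments reaching significance at spec.alpha.

    ``delta`` overrides the effect size in ``config.spec`` (the spec type
    requires delta > 0; pass ``delta=0`` here to check the type-I error
    rate).  Deterministic given ``config.seed``.
    """
    spec = config.spec
    if delta is None:
        delta = spec.delta
    sigma_X2 = config.sigma_X2
    comps = decompose_observed(sigma_X2, config.rho)
    rng = np.random.default_rng(config.seed)
    n, reps = spec.N, config.reps
    sd_T, sd_E = math.sqrt(comps.sigma_T2), math.sqrt(comps.sigma_E2)

    # spec.sigma is ignored: the scenario fixes the observed variance, and the
    # critical value below is recomputed on the same df/tails as spec.
    crit_spec = PowerSpec(
        N=n, delta=1.0, alpha=spec.alpha, sigma=1.0, tails=spec.tails, formula=spec.formula
    )
    t_crit = crit_spec.t_crit

    if spec.formula == "paper":
        scores = delta + rng.normal(0.0, sd_T, (reps, n)) + rng.normal(0.0, sd_E, (reps, n))
        t = _t_one_sample(scores)
    else:
        g1 = rng.normal(0.0, sd_T, (reps, n)) + rng.normal(0.0, sd_E, (reps, n))
        g2 = delta + rng.normal(0.0, sd_T, (reps, n)) + rng.normal(0.0, sd_E, (reps, n))
        # pooled two-sample t with equal n: se = sp * sqrt(2/n)
        v1 = g1.var(axis=1, ddof=1)
        v2 = g2.var(axis=1, ddof=1)
        sp2 = (v1 + v2) / 2.0
        t = (g2.mean(axis=1) - g1.mean(axis=1)) / np.sqrt(sp2 * 2.0 / n)

    if spec.tails == "one_sided":
        sig = t > t_crit
    else:
        sig = np.abs(t) > t_crit
    p_sig = float(sig.mean())
    mc_se = math.sqrt(p_sig * (1.0 - p_sig) / reps)
    return MCResult(p_sig=p_sig, reps=reps, mc_se=mc_se, seed=config.seed)
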