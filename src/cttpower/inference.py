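"""Welch two-group comparison and per-group error-variance reporting.

The Welch (unequal-variances) t-test compares two group means without
assuming a common variance:

    t  = (m2 - m1) / sqrt(s1^2/n1 + s2^2/n2)
    df = (s1^2/n1 + s2^2/n2)^2 / [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ]

with df the Welch-Satterthwaite approximation, bounded between
min(n1, n2) - 1 and n1 + n2 - 2.  The error-variance report combines group
summaries with reliability estimates to decompose each group's observed
variance into true- and error-score components (sigma_E^2 = sigma_X^2 -
rho * sigma_X^2) — the arithmetic that shows a group can have lower
reliability yet *less* measurement error, when its true-score variance is
small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ctt import VarianceComponents, decompose_observed, display_round
from .errors import DegenerateDataError

__all__ = [
    "GroupSummary",
    "WelchResult",
    "welch_from_summaries",
    "welch_from_scores",
    "group_error_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD (n-1 denominator) of one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")

    @property
    def variance(self) -> float:
        return self.sd * self.sd

    @classmethod
    def from_scores(cls, label: str, scores: Sequence[float]) -> "GroupSummary":
        x = np.asarray(scores, dtype=float)
        if x.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 scores, got {x.size}")
        return cls(label=label, n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))

    def as_dict(self) -> dict:
        return {"label": self.label, "n": self.n, "mean": self.mean, "sd": self.sd,
                "variance": self.variance}


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    tails: str
    group1: GroupSummary
    group2: GroupSummary

    def as_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "tails": self.tails,
            "groups": [self.group1.as_dict(), self.group2.as_dict()],
        }


def welch_from_summaries(
    g1: GroupSummary, g2: GroupSummary, tails: str = "two_sided"
) -> WelchResult:
    """Welch's t-test from group summary statistics.

    The statistic is (g2.mean - g1.mean) over the unpooled standard error;
    one-sided tests the alternative mean2 > mean1.
    """
    if tails not in ("one_sided", "two_sided"):
        raise ValueError(f"tails must be one_sided or two_sided, got {tails!r}")
    se1 = g1.variance / g1.n
    se2 = g2.variance / g2.n
    se2_total = se1 + se2
    if se2_total == 0.0:
        raise DegenerateDataError("both group variances are zero; t undefined")
    t = (g2.mean - g1.mean) / np.sqrt(se2_total)
    df = se2_total**2 / (se1**2 / (g1.n - 1) + se2**2 / (g2.n - 1))
    if tails == "two_sided":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(t, df))
    return WelchResult(t=float(t), df=float(df), p=min(p, 1.0), tails=tails,
                       group1=g1, group2=g2)


def welch_from_scores(
    scores1: Sequence[float],
    scores2: Sequence[float],
    tails: str = "two_sided",
    labels: tuple[str, str] = ("group1", "group2"),
) -> WelchResult:
    """Welch's t-test from raw per-participant scores."""
    g1 = GroupSummary.from_scores(labels[0], scores1)
    g2 = GroupSummary.from_scores(labels[1], scores2)
    return welch_from_summaries(g1, g2, tails=tails)


def group_error_report(
    summaries: Sequence[GroupSummary],
    reliabilities: Sequence[float],
    observed_variances: Sequence[float] | None = None,
) -> list[dict]:
    """Per-group variance decomposition given reliability estimates.

    Each entry pairs a group's observed variance with its reliability and
    reports sigma_T^2 and sigma_E^2, both raw and rounded half-away-from-zero
    to 3 decimals for display.  ``observed_variances`` overrides the variance
    implied by each summary's SD — useful when the variance is quoted at a
    coarser precision than the SD (e.g. 0.31 vs 0.55^2 = 0.3025).
    """
    if len(summaries) != len(reliabilities):
        raise ValueError(
            f"got {len(summaries)} summaries but {len(reliabilities)} reliabilities"
        )
    if observed_variances is not None and len(observed_variances) != len(summaries):
        raise ValueError("observed_variances length must match summaries")
    report = []
    for i, (g, rho) in enumerate(zip(summaries, reliabilities)):
        var = g.variance if observed_variances is None else observed_variances[i]
        comps: VarianceComponents = decompose_observed(var, rho)
        report.append(
            {
                "label": g.label,
                "n": g.n,
                "mean": g.mean,
                "sd": g.sd,
                "sigma_X2": comps.sigma_X2,
                "rho": rho,
                "sigma_T2": comps.sigma_T2,
                "sigma_E2": comps.sigma_E2,
                "sigma_T2_display": display_round(comps.sigma_T2),
                "sigma_E2_display": display_round(comps.sigma_E2),
            }
        )
    return report
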