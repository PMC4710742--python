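"""Synthetic two-condition IAT experiment generator.

Emulates a hypothetical instruction-based evaluative-learning study: thirty
participants receive attitude-relevant instructions ("Luupites are good and
Niffites are bad"), thirty receive attitude-irrelevant instructions, and all
complete an IAT whose effect score is taken directly on the IAT-effect
scale (no latency simulation or D-score algorithm).

Generating model, per participant i in condition c with population mean
mu_c, observed variance sigma_X2_c and reliability rho_c:

    T_ic      ~ Normal(mu_c, rho_c * sigma_X2_c)          (true score)
    score_ict = T_ic + eps_ict,  eps ~ Normal(0, K * sigma_E2_c)

with K the total trial count and sigma_E2_c = (1 - rho_c) * sigma_X2_c.
The mean of the K trials then has error variance sigma_E2_c, so the
full score has variance sigma_X2_c and reliability rho_c in expectation,
and the mean of a half of the trials has error variance 2 * sigma_E2_c —
exactly the structure split-half estimation assumes.

Trials are tagged practice/test in equal blocks; block labels are metadata
only (the full score pools practice and test trials).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError

__all__ = [
    "ConditionSpec",
    "TrialTable",
    "default_condition_specs",
    "PRINTED_MOMENTS",
    "generate_experiment",
    "full_scores",
    "moment_match",
]

_COLUMNS = ["participant_id", "condition", "block", "trial_index", "score"]

#: Printed per-condition sample moments (mean, SD) of the worked example.
PRINTED_MOMENTS: dict[str, tuple[float, float]] = {
    "attitude_irrelevant": (-0.25, 0.55),
    "attitude_relevant": (0.68, 0.22),
}


@dataclass(frozen=True)
class ConditionSpec:
    """Population parameters for one experimental condition.

    ``trials_per_block`` is the number of trials in each of the practice and
    test blocks, so the full score averages ``2 * trials_per_block`` trials.
    """

    label: str
    mu: float
    sigma_X2: float
    rho: float
    n: int = 30
    trials_per_block: int = 20

    def __post_init__(self) -> None:
        if not self.sigma_X2 > 0:
            raise ValueError(f"sigma_X2 must be > 0, got {self.sigma_X2}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")
        if (2 * self.trials_per_block) % 2 != 0:  # guaranteed, but total must split
            raise ValueError("total trial count must be even")

    @property
    def n_trials(self) -> int:
        return 2 * self.trials_per_block

    @property
    def sigma_T2(self) -> float:
        return self.rho * self.sigma_X2

    @property
    def sigma_E2(self) -> float:
        return self.sigma_X2 - self.sigma_T2


def default_condition_specs() -> tuple[ConditionSpec, ConditionSpec]:
    """The worked example's two conditions, calibrated from the printed values.

    Observed variances 0.31 / 0.05 with reliabilities 0.92 / 0.57 and n = 30
    per condition.  The printed variances are taken as canonical even though
    they differ at the third decimal from the squared printed SDs
    (0.55^2 = 0.3025, 0.22^2 = 0.0484).
    """
    return (
        ConditionSpec(label="attitude_irrelevant", mu=-0.25, sigma_X2=0.31, rho=0.92),
        ConditionSpec(label="attitude_relevant", mu=0.68, sigma_X2=0.05, rho=0.57),
    )


@dataclass(frozen=True)
class TrialTable:
    """Long-format trial-level scores plus generation metadata.

    ``data`` columns: participant_id, condition, block (practice|test),
    trial_index, score.  Participant ids are unique across conditions.
    """

    data: pd.DataFrame = field(repr=False)
    seed: int | None = None
    specs: tuple[ConditionSpec, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        counts = self.data.groupby("participant_id", sort=False)["score"].size()
        if counts.nunique() > 1:
            raise ValueError("every participant must have the same trial count")
        if int(counts.iloc[0]) % 2 != 0:
            raise ValueError("trial count per participant must be even (splittable)")
        if self.data["score"].isna().any():
            raise ValueError("trial table contains missing scores")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.data["condition"].unique())

    @property
    def n_trials(self) -> int:
        return int(self.data.groupby("participant_id", sort=False)["score"].size().iloc[0])

    def wide(self, condition: str | None = None) -> pd.DataFrame:
        """Participants x trials score matrix (rows indexed by participant_id)."""
        d = self.data if condition is None else self.data[self.data["condition"] == condition]
        if d.empty:
            raise ValueError(f"no rows for condition {condition!r}")
        return d.pivot(index="participant_id", columns="trial_index", values="score")

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        return cls(data=pd.read_csv(path))

    def config_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "specs": [vars(s) | {"n_trials": s.n_trials} for s in self.specs],
            },
            indent=2,
        )


def generate_experiment(
    specs: Sequence[ConditionSpec] | None = None, seed: int = 0
) -> TrialTable:
    """Draw a full synthetic experiment. Deterministic given ``seed``."""
    if specs is None:
        specs = default_condition_specs()
    if not specs:
        raise ValueError("at least one condition spec required")
    rng = np.random.default_rng(seed)
    frames = []
    pid_offset = 0
    for spec in specs:
        K = spec.n_trials
        true = rng.normal(spec.mu, math.sqrt(spec.sigma_T2), spec.n)
        noise = rng.normal(0.0, math.sqrt(K * spec.sigma_E2), (spec.n, K))
        scores = true[:, None] + noise
        pids = np.repeat(np.arange(pid_offset, pid_offset + spec.n), K)
        trial_idx = np.tile(np.arange(K), spec.n)
        block = np.where(trial_idx < spec.trials_per_block, "practice", "test")
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pids,
                    "condition": spec.label,
                    "block": block,
                    "trial_index": trial_idx,
                    "score": scores.ravel(),
                }
            )
        )
        pid_offset += spec.n
    table = pd.concat(frames, ignore_index=True)
    return TrialTable(data=table, seed=seed, specs=tuple(specs))


def full_scores(table: TrialTable) -> pd.DataFrame:
    """Per-participant full IAT score: the mean over all trials.

    Returns a DataFrame with columns participant_id, condition, score.
    """
    out = (
        table.data.groupby(["participant_id", "condition"], sort=False)["score"]
        .mean()
        .reset_index()
    )
    return out


def moment_match(
    table: TrialTable, targets: Mapping[str, tuple[float, float]] | None = None
) -> TrialTable:
    """Affine-rescale each condition so full-score sample moments hit targets exactly.

    For condition c with current full-score sample mean m and SD s (n-1
    denominator) and target (m*, s*), every trial score is mapped through
    x -> (s*/s) * (x - m) + m*.  Participant full scores then have sample
    mean m* and SD s* exactly; within-participant trial structure is
    preserved up to this common affine map.  Opt-in mode for reproducing
    printed summary arithmetic — the rescaling slightly distorts the
    population reliability calibration.
    """
    if targets is None:
        targets = PRINTED_MOMENTS
    fs = full_scores(table)
    data = table.data.copy()
    for cond, (m_target, s_target) in targets.items():
        if not math.isfinite(m_target) or not math.isfinite(s_target) or s_target <= 0:
            raise ValueError(f"invalid targets for {cond!r}: {(m_target, s_target)}")
        cur = fs.loc[fs["condition"] == cond, "score"]
        if cur.empty:
            raise ValueError(f"no participants in condition {cond!r}")
        m, s = float(cur.mean()), float(cur.std(ddof=1))
        if s == 0.0 or not math.isfinite(s):
            raise DegenerateDataError(
                f"zero full-score variance in {cond!r}; cannot moment-match"
            )
        a = s_target / s
        mask = data["condition"] == cond
        data.loc[mask, "score"] = a * (data.loc[mask, "score"] - m) + m_target
    return TrialTable(data=data, seed=table.seed, specs=table.specs)
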