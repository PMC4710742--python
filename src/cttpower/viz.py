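"""Optional figure rendering (headless-safe; data files remain canonical)."""

from __future__ import annotations

from pathlib import Path

from .power import PowerSurface
from .simulate import TrialTable


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_power_curves(surface: PowerSurface, path: str | Path) -> None:
    """Power vs reliability, one line per sample size."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for j, n in enumerate(surface.N_grid):
        ax.plot(surface.rho_grid, surface.power[:, j], marker="o", label=f"N = {n}")
    fixed = "true-score" if surface.scenario == "fixed_true" else "error-score"
    ax.set_xlabel(r"reliability $\rho_{XX'}$")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1.02)
    ax.set_title(
        f"Exact power vs reliability, {fixed} variance fixed at 1.00\n"
        rf"($\delta$={surface.delta}, $\alpha$={surface.alpha}, {surface.tails}, "
        f"{surface.formula})"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_half_scatter(table: TrialTable, path: str | Path) -> None:
    """Practice-half vs test-half mean score per participant, by condition."""
    plt = _pyplot()
    d = table.data
    halves = (
        d.groupby(["participant_id", "condition", "block"])["score"].mean().unstack("block")
    )
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for cond, marker in zip(sorted(d["condition"].unique()), ("o", "s", "^", "D")):
        sub = halves.xs(cond, level="condition")
        ax.scatter(sub["practice"], sub["test"], marker=marker, alpha=0.8, label=cond)
    ax.set_xlabel("practice-trials IAT score")
    ax.set_ylabel("test-trials IAT score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
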