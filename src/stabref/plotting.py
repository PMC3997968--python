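"""Minimal bar/line exports of geNorm M and V series (SVG)."""

from __future__ import annotations

from pathlib import Path

from .genorm import PairwiseVariationSeries, StabilityRanking

__all__ = ["plot_m_series", "plot_v_series"]


def plot_m_series(ranking: StabilityRanking, path: str | Path) -> None:
    """Average stability M of remaining genes at each exclusion stage."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stages = ranking.m_by_stage
    xs = list(range(len(stages)))
    ys = [float(m.mean()) for m in stages]
    labels = ["all"] + [f"-{g}" for g in ranking.exclusion_order]
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(xs, ys, marker="o")
    ax.set_xticks(xs, labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("average expression stability M")
    ax.set_xlabel("stepwise exclusion")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_v_series(v: PairwiseVariationSeries, path: str | Path) -> None:
    """Pairwise variation V(n/n+1) bars with the decision cut-off."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ns = sorted(v.v_values)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar([f"V{n}/{n + 1}" for n in ns], [v.v_values[n] for n in ns])
    ax.axhline(v.cutoff, color="crimson", linestyle="--", label=f"cut-off {v.cutoff}")
    ax.set_ylabel("pairwise variation V")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
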