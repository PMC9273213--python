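"""Dot-plot of per-cell PCCs per condition (mean bar, SEM whisker, cell dots)."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .containers import ConditionSummary


def plot_condition_dotplot(
    summaries: Sequence[ConditionSummary],
    ax=None,
    jitter: float = 0.12,
    seed: int = 0,
):
    """Per-condition scatter of individual-cell PCC values.

    Each condition gets a column of jittered dots (one per cell), a
    horizontal mean bar and an SEM whisker.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(1.2 * max(len(summaries), 2) + 1, 4))
    rng = np.random.default_rng(seed)
    for i, s in enumerate(summaries):
        x = i + rng.uniform(-jitter, jitter, size=len(s.values))
        ax.plot(x, s.values, "o", ms=4, alpha=0.6, zorder=1)
        ax.hlines(s.mean_pcc, i - 0.25, i + 0.25, color="k", lw=2, zorder=2)
        if np.isfinite(s.sem_pcc):
            ax.errorbar(i, s.mean_pcc, yerr=s.sem_pcc, color="k", capsize=4, zorder=2)
    ax.set_xticks(range(len(summaries)))
    ax.set_xticklabels([s.condition for s in summaries], rotation=20, ha="right")
    ax.set_ylabel("per-cell PCC (reporter vs mitochondria)")
    ax.axhline(0, color="0.8", lw=0.8, zorder=0)
    return ax
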