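"""Diagnostic plot: prior, signal and posterior densities for one cell.

Mirrors the classic cue-fusion illustration: thin grey curve for the
grey-disk signal, blue for the typical-colour prior, thick red for the
fused posterior, and a dashed vertical line at the measured effect
(negated so it sits on the posterior's side of grey).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import stats

from .model import CueEstimate, PosteriorPrediction

__all__ = ["plot_cell_model"]


def plot_cell_model(
    prior: CueEstimate,
    signal: CueEstimate,
    posterior: PosteriorPrediction,
    measured: float | None = None,
    title: str = "",
    path: str | Path | None = None,
):
    """Plot the two cue densities and the fused posterior; optionally
    save to ``path``.  Returns the matplotlib Axes."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sds = [np.sqrt(max(prior.variance, 1e-12)),
           np.sqrt(max(signal.variance, 1e-12)), max(posterior.sd, 1e-6)]
    lo = min(prior.mean, signal.mean, posterior.M) - 4 * max(sds)
    hi = max(prior.mean, signal.mean, posterior.M) + 4 * max(sds)
    x = np.linspace(lo, hi, 512)

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(x, stats.norm.pdf(x, signal.mean, sds[1]), color="0.6", lw=1,
            label="signal (disk greys)")
    ax.plot(x, stats.norm.pdf(x, prior.mean, sds[0]), color="tab:blue", lw=1,
            label="prior (typicals)")
    ax.plot(x, stats.norm.pdf(x, posterior.M, sds[2]), color="tab:red", lw=2,
            label="posterior")
    if measured is not None:
        ax.axvline(measured, color="k", ls=":", label="measured effect")
    ax.set_xlabel("projection onto typical-hue axis")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
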