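"""Diagnostic figures: regression scatter+curve and an RDA biplot.

Plots are intentionally plain; they exist so a pipeline run can be eyeballed,
not to reproduce publication figure aesthetics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .core import StumpSample
from .ordination import RDAResult
from .regression import RegressionFit, _response_vector


def plot_fit(samples: Sequence[StumpSample], fit: RegressionFit,
             path: str | Path) -> None:
    """Scatter of the response against ergosterol with the fitted curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = list(samples)
    x = np.array([s.ergosterol_ug_g for s in samples])
    y = _response_vector(samples, fit.response_label)
    grid = np.linspace(x.min(), x.max(), 200)
    if fit.model_form == "linear":
        curve = fit.a + fit.b * grid
    else:
        curve = fit.a * np.exp(fit.b * grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.7, edgecolor="none")
    ax.plot(grid, curve, color="crimson")
    ax.set_xlabel("ergosterol (µg/g d.m.)")
    ax.set_ylabel(fit.response_label)
    ax.set_title(f"{fit.response_label}: {fit.model_form}, "
                 f"r²={fit.r2:.2f}, p_adj={fit.p_adjusted:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rda_biplot(result: RDAResult, path: str | Path,
                    scale: float = 1.0) -> None:
    """Sites on axes 1–2 with element loadings drawn as arrows."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = result.site_scores
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.scatter(scores[:, 0], scores[:, 1], s=16, alpha=0.6, edgecolor="none")
    reach = np.abs(scores[:, :2]).max() or 1.0
    for el, loading in result.axis1_loadings.items():
        ax.annotate(el, (loading * reach * scale, 0),
                    xytext=(0, 0), textcoords="data",
                    arrowprops=dict(arrowstyle="<-", color="gray", lw=0.8))
    frac = result.variance_fractions
    ax.set_xlabel(f"RDA1 (constrained, {100 * frac[0]:.1f}%)")
    ax.set_ylabel(f"PC1 of residuals ({100 * frac[1]:.1f}%)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_title(f"single-constraint RDA, perm p = {result.perm_p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
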