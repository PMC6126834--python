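"""Optional rendering of Q-Q and fold-enrichment figures (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_qq(pvals_by_label: dict, ax=None, max_points: int = 10_000):
    """Stratified Q-Q plot: one curve per labelled p-value collection."""
    from .enrichment_curves import qq_points

    if ax is None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(4.5, 4.5))
    top = 0.0
    for label, p in pvals_by_label.items():
        exp, obs = qq_points(p)
        if exp.size > max_points:  # thin dense null tails for rendering only
            idx = np.unique(np.geomspace(1, exp.size, max_points).astype(int)) - 1
            exp, obs = exp[idx], obs[idx]
        ax.plot(exp, obs, label=label, lw=1.2)
        top = max(top, exp.max(), obs.max())
    ax.plot([0, top], [0, top], color="grey", lw=0.8, ls="--")
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    ax.legend(fontsize=8)
    return ax


def plot_fold_curve(curves: dict, ax=None):
    """Fold-enrichment curves on a log scale, one per labelled FoldCurve."""
    if ax is None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for label, curve in curves.items():
        ax.plot(curve.thresholds, curve.ratio, label=label, lw=1.2)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yscale("log")
    ax.set_xlabel(r"association $-\log_{10}(p)$ threshold (bin centers)")
    ax.set_ylabel("fold enrichment (CDF ratio)")
    ax.legend(fontsize=8)
    return ax
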