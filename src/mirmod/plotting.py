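"""Optional matplotlib conveniences: preservation scatter and ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_zsummary(results, ax=None):
    """Z_summary vs module size scatter with the 2 / 10 threshold lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = results.table
    ax.scatter(t["size"], t["Z_summary"], c="tab:blue")
    for m, row in t.iterrows():
        ax.annotate(str(m), (row["size"], row["Z_summary"]),
                    fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.axhline(2, color="tab:blue", ls="--", lw=0.8)
    ax.axhline(10, color="tab:green", ls="--", lw=0.8)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("module size")
    ax.set_ylabel("Z_summary")
    return ax


def plot_roc(results, ax=None):
    """ROC curves for one or more diagnostic results."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    if not isinstance(results, (list, tuple)):
        results = [results]
    for r in results:
        pts = r.roc.points
        ax.plot(pts["fpr"], pts["tpr"],
                label=f"{r.name} (AUC={r.auc:.3f})")
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8, ls=":")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    return ax
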