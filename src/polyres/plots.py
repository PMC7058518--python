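"""QQ and forest plots for scan and per-bin results."""

from __future__ import annotations

import numpy as np

from .assoc import qq_points


def qq_plot(pvals, ax=None, **scatter_kw):
    """Quantile-quantile plot of -log10 p-values against the uniform null."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    exp, obs = qq_points(pvals)
    ax.scatter(exp, obs, s=scatter_kw.pop("s", 8), **scatter_kw)
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    return ax


def forest_plot(table, ax=None, label_col="cutoff", beta_col="beta", se_col="se"):
    """Forest plot of per-bin odds ratios with 95% CIs (log scale)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    t = table.reset_index(drop=True)
    ypos = np.arange(len(t))[::-1]
    or_ = np.exp(t[beta_col])
    lo = np.exp(t[beta_col] - 1.96 * t[se_col])
    hi = np.exp(t[beta_col] + 1.96 * t[se_col])
    ax.errorbar(or_, ypos, xerr=[or_ - lo, hi - or_], fmt="o", capsize=3)
    ax.axvline(1.0, color="grey", lw=1, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels([f"p < {c}" for c in t[label_col]])
    ax.set_xlabel("OR per SD of resilience score")
    return ax
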