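"""Optional diagnostic plots for the comparison report."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .comparison_stats import ModelComparisonResult, bland_altman


def plot_bland_altman(gold: Sequence[float], method: Sequence[float], ax=None, label: str = ""):
    """Bland-Altman plot: differences vs pairwise means with bias, limits of
    agreement and the bias-vs-burden trend line."""
    import matplotlib.pyplot as plt

    g = np.asarray(gold, dtype=float)
    m = np.asarray(method, dtype=float)
    res = bland_altman(g, m)
    mean = 0.5 * (g + m)
    diff = m - g
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mean, diff, s=18, alpha=0.7)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="grey", linestyle=style, linewidth=1)
    xs = np.linspace(mean.min(), mean.max(), 50)
    ax.plot(xs, res.trend_intercept + res.trend_slope * xs, color="firebrick",
            linewidth=1, label=f"trend slope {res.trend_slope:.2f}")
    ax.set_xlabel("(method + gold standard) / 2")
    ax.set_ylabel("method − gold standard")
    if label:
        ax.set_title(label)
    ax.legend(frameon=False)
    return ax


def plot_annual_change(
    baseline: Sequence[float],
    annual_change: Sequence[float],
    model: ModelComparisonResult | None = None,
    ax=None,
    label: str = "",
):
    """Baseline burden vs annual % change, with the fitted linear and
    quadratic curves (the AIC-preferred one drawn solid)."""
    import matplotlib.pyplot as plt

    x = np.asarray(baseline, dtype=float)
    y = np.asarray(annual_change, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(x, y, s=18, alpha=0.7)
    if model is not None:
        xs = np.linspace(x.min(), x.max(), 100)
        lin = np.polyval(model.coef_linear[::-1], xs)
        quad = np.polyval(model.coef_quadratic[::-1], xs)
        lin_style = "-" if model.preferred == "linear" else "--"
        quad_style = "-" if model.preferred == "quadratic" else "--"
        ax.plot(xs, lin, lin_style, color="steelblue", label="linear")
        ax.plot(xs, quad, quad_style, color="firebrick",
                label=f"quadratic (ΔAIC {model.delta_aic:.1f})")
        ax.legend(frameon=False)
    ax.set_xlabel("baseline value")
    ax.set_ylabel("annual change (%/year)")
    if label:
        ax.set_title(label)
    return ax
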