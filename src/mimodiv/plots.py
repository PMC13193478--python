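"""Summary figures for the three analysis stages."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_rate_timeline", "plot_regime_parameters"]

_COLORS = {"evergreen": "#2a7e43", "deciduous": "#c4731d"}


def plot_rate_timeline(fit, ax=None):
    """Step plot of per-epoch speciation and transition rates over time.

    Takes an SSEFit; epochs are drawn backward from the present with the
    slice age marked, one line per observed state.
    """
    from mimodiv.sse import rate_summary

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tab = rate_summary(fit)
    slice_age = fit.spec.slice_age if fit.spec.sliced else None
    t_max = 2 * slice_age if slice_age else 10.0
    for state, sub in tab.groupby("state"):
        color = _COLORS.get(state, None)
        for kind, style in (("speciation", "-"), ("transition_out", "--")):
            if slice_age:
                early = sub[sub["epoch"] == "early"][kind].iloc[0]
                late = sub[sub["epoch"] == "late"][kind].iloc[0]
                ax.step([t_max, slice_age, 0], [early, late, late], style,
                        where="post", color=color,
                        label=f"{state} {kind.replace('_out', '')}")
            else:
                rate = sub[kind].iloc[0]
                ax.plot([t_max, 0], [rate, rate], style, color=color,
                        label=f"{state} {kind.replace('_out', '')}")
    if slice_age:
        ax.axvline(slice_age, color="gray", linestyle=":", lw=1)
    ax.set_xlabel("age (Myr before present)")
    ax.set_ylabel("rate (Myr$^{-1}$)")
    ax.invert_xaxis()
    ax.legend(fontsize=8)
    return ax


def plot_regime_parameters(fits_by_variable: dict, ax=None):
    """Dot plot of the best model's per-regime (sigma^2, alpha, theta) per
    environmental variable (fits_by_variable: name -> list of NicheFit)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rows = []
    for var, fits in fits_by_variable.items():
        best = min(fits, key=lambda f: f.aicc)
        rows.append((var, best))
    y = np.arange(len(rows))
    for offset, regime, label in ((-0.15, 0, "evergreen"), (0.15, 1, "deciduous")):
        ax.scatter(
            [b.params.sigma2[regime] for _, b in rows], y + offset,
            color=_COLORS[label], label=f"{label} $\\sigma^2$", marker="o",
        )
    ax.set_yticks(y, [f"{v} ({b.spec.name})" for v, b in rows])
    ax.set_xlabel("evolutionary rate $\\sigma^2$ (scaled trait$^2$ Myr$^{-1}$)")
    ax.legend(fontsize=8)
    return ax
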