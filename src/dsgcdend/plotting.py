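"""Small matplotlib helpers for the standard figures of this pipeline."""

from __future__ import annotations

import numpy as np

__all__ = ["polar_tuning_plot", "decay_curve_plot"]


def polar_tuning_plot(R, theta_deg, ax=None, **kwargs):
    """Closed polar tuning curve with the vector-sum arrow overlaid."""
    import matplotlib.pyplot as plt

    from .tuning import vector_sum_tuning

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    th = np.deg2rad(np.append(theta_deg, theta_deg[0]))
    rr = np.append(R, R[0])
    ax.plot(th, rr, **kwargs)
    tr = vector_sum_tuning(np.clip(R, 0, None), theta_deg)
    if np.isfinite(tr.preferred_angle_deg):
        ax.annotate("", xy=(np.deg2rad(tr.preferred_angle_deg),
                            tr.dsi * max(np.max(R), 1e-9)),
                    xytext=(0, 0), arrowprops={"arrowstyle": "->"})
    return ax


def decay_curve_plot(pairs, fit=None, ax=None):
    """Peak correlation vs cable distance: points, binned means, optional fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pairs["distance_um"], pairs["peak_corr"], ".", alpha=0.2,
            label="pairs")
    if fit is not None:
        ax.errorbar(fit.binned["bin_center_um"], fit.binned["mean"],
                    yerr=fit.binned["sem"], fmt="o", label="2 µm bins")
        if fit.converged:
            d = np.linspace(0, pairs["distance_um"].max(), 200)
            ax.plot(d, fit.amplitude * np.exp(-d / fit.lambda_um) + fit.floor,
                    "r-", label=f"λ = {fit.lambda_um:.1f} µm")
    ax.set_xlabel("cable distance (µm)")
    ax.set_ylabel("peak correlation")
    ax.legend()
    return ax
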