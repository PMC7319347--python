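"""Interaction plots: fitted outcome lines for low/high moderator levels
over the environment range, with vertical region-of-significance bounds."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def interaction_plot(data, spec, fit, report: dict, path) -> None:
    """Two fitted lines (moderator at mean -/+ 1 SD), RoS bounds as vertical
    lines, and the observed scatter, written to SVG/PNG by extension."""
    x = data[spec.environment].astype(float)
    y = data[spec.outcome].astype(float)
    z = data[spec.moderator].astype(float)
    xm, xs = x.mean(), x.std(ddof=1)
    grid = np.linspace(xm - 2 * xs, xm + 2 * xs, 100)
    b = fit.params
    covs = {c: data[c].astype(float).mean() for c in spec.covariates}
    base = b["const"] + sum(b[c] * v for c, v in covs.items())

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for level, label, color in (
        (z.mean() - z.std(ddof=1), "low moderator (-1 SD)", "#c44e52"),
        (z.mean() + z.std(ddof=1), "high moderator (+1 SD)", "#4c72b0"),
    ):
        line = (
            base
            + b[spec.moderator] * level
            + b[spec.environment] * grid
            + b[spec.interaction] * level * grid
        )
        ax.plot(grid, line, label=label, color=color)
    ax.scatter(x, y, s=12, alpha=0.35, color="gray", linewidths=0)
    ros = report["ros"]
    for bound in (ros.get("lower"), ros.get("upper")):
        if bound is not None:
            ax.axvline(bound, linestyle="--", color="black", linewidth=1)
    ax.set_xlabel(spec.environment)
    ax.set_ylabel(spec.outcome)
    ax.set_title(f"{spec.outcome}: verdict {report['verdict']['verdict']}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
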