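"""Non-interactive phasor-plane and contribution-map figures."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.patches import Ellipse  # noqa: E402

from .geometry import PhasorFitResult  # noqa: E402
from .model import PhasorCloud  # noqa: E402

__all__ = ["phasor_plot"]


def _draw_semicircle(ax) -> None:
    theta = np.linspace(0.0, math.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta),
            color="0.4", lw=1.0, zorder=1)
    ax.axhline(0.0, color="0.8", lw=0.5)


def _draw_result(ax, result: PhasorFitResult, color: str) -> None:
    ell = result.ellipse
    ax.add_patch(Ellipse(
        ell.center, 2 * ell.a, 2 * ell.b,
        angle=math.degrees(ell.orientation),
        fill=False, edgecolor=color, lw=1.5, zorder=4,
    ))
    if result.is_mono or result.pair is None:
        return
    p1, p2 = np.asarray(result.pair.p1), np.asarray(result.pair.p2)
    ax.plot([p1[0], p2[0]], [p1[1], p2[1]], color=color, lw=1.0, zorder=3)
    ax.scatter(*zip(p1, p2), marker="x", s=60, color=color, zorder=5)


def phasor_plot(
    clouds: dict[str, PhasorCloud],
    results: dict[str, PhasorFitResult] | None = None,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Scatter one or more phasor clouds with the universal semicircle.

    For each labelled cloud, the matching entry in ``results`` (if any)
    contributes its confidence ellipse, fitted chord and circle
    intersections.  Saved to ``path`` when given, else the figure is
    returned for further handling.
    """
    results = results or {}
    fig, ax = plt.subplots(figsize=(6, 3.6))
    cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, (label, cloud) in enumerate(clouds.items()):
        color = cycle[i % len(cycle)]
        ax.scatter(cloud.g, cloud.s, s=2, alpha=0.4, color=color,
                   label=label, zorder=2)
        if label in results:
            _draw_result(ax, results[label], color)
    _draw_semicircle(ax)
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 0.6)
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    if clouds:
        ax.legend(loc="upper right", fontsize=8, markerscale=4)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
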