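"""Basic plots: EGA network, person-item map, test curves, DTF curves.

Each function draws on a provided matplotlib Axes (or creates one) and
returns it; the pipeline writes them as PNG files next to the TSV
tables.  Styling is intentionally minimal — the TSV outputs carry the
plot-ready data for custom figures.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_network(result, ax=None):
    """EGA partial-correlation network; edge width ~ |partial r|,
    node color = community."""
    ax = ax or plt.subplots(figsize=(5, 5))[1]
    p = result.network.shape[0]
    angles = 2 * np.pi * np.arange(p) / p
    xy = np.column_stack([np.cos(angles), np.sin(angles)])
    for i in range(p):
        for j in range(i + 1, p):
            wgt = result.network[i, j]
            if abs(wgt) > 1e-10:
                ax.plot(*zip(xy[i], xy[j]), lw=6 * abs(wgt),
                        color="tab:green" if wgt > 0 else "tab:red",
                        alpha=0.7, zorder=1)
    colors = plt.cm.tab10(result.membership % 10)
    ax.scatter(xy[:, 0], xy[:, 1], s=600, c=colors, zorder=2,
               edgecolor="k")
    for i, name in enumerate(result.item_names):
        ax.annotate(name, 1.18 * xy[i], ha="center", va="center", fontsize=8)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_axis_off()
    return ax


def plot_person_item_map(fit, ax=None):
    """Wright map: EAP histogram above, item threshold locations below."""
    from .grm import person_item_map

    wm = person_item_map(fit)
    ax = ax or plt.subplots(figsize=(6, 4))[1]
    centers = 0.5 * (wm["bin_edges"][:-1] + wm["bin_edges"][1:])
    ax.bar(centers, wm["hist"] / wm["hist"].sum(),
           width=np.diff(wm["bin_edges"]), color="0.7")
    items = list(wm["thresholds"])
    for pos, name in enumerate(items):
        y = -0.02 * (pos + 1)
        ax.plot(wm["thresholds"][name], np.full(len(wm["thresholds"][name]), y),
                "|", ms=8)
        ax.annotate(name, (wm["theta_range"][1], y), fontsize=7, va="center")
    ax.set_xlabel("latent trait")
    ax.set_ylabel("share of respondents")
    return ax


def plot_test_curves(params, ax=None):
    """TCC and TIF over the latent-trait lattice."""
    from .grm import information, test_curves

    ax = ax or plt.subplots(figsize=(6, 4))[1]
    curves = test_curves(params)
    info = information(params)
    ax.plot(curves["theta"], curves["tcc"], label="expected test score")
    ax2 = ax.twinx()
    ax2.plot(info["theta"], info["tif"], color="tab:orange", label="information")
    ax.set_xlabel("latent trait")
    ax.set_ylabel("expected test score")
    ax2.set_ylabel("test information")
    return ax


def plot_dtf_curve(drf_result, ax=None):
    """Expected-test-score difference between two groups with 99% CI."""
    ax = ax or plt.subplots(figsize=(6, 4))[1]
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.plot(drf_result.theta, drf_result.difference,
            label=f"{drf_result.reference} - {drf_result.focal}")
    if drf_result.difference_ci is not None:
        ax.fill_between(drf_result.theta, drf_result.difference_ci[:, 0],
                        drf_result.difference_ci[:, 1], alpha=0.25)
    ax.set_xlabel("latent trait")
    ax.set_ylabel("expected test score difference")
    ax.legend(fontsize=8)
    return ax


def savefig(ax, path):
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
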