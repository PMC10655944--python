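"""Figure-type computations and rendering: box plots, ordination scatters,
and landmark deformation diagrams.

Every plot is backed by a plain-numbers computation (summary statistics,
displacement fields, group mean configurations) that can be exported as CSV
and asserted on directly; rendering to SVG/PNG is a thin matplotlib layer on
top.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def regress_shape_on_axis(tangent: np.ndarray,
                          axis_scores: Sequence[float]) -> np.ndarray:
    """Per-landmark displacement field per unit score along an axis.

    Ordinary least-squares slope of each tangent coordinate on the axis
    score, reshaped to (k, 2).  The intercept is the mean shape, so the
    deformation along the axis is mean + score * field.
    """
    x = np.asarray(axis_scores, dtype=float)
    y = np.atleast_2d(np.asarray(tangent, dtype=float))
    if y.shape[0] != x.size:
        raise ValueError("axis_scores length must match rows of tangent")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx == 0.0:
        raise ValueError("axis_scores are constant")
    slope = (xc @ (y - y.mean(axis=0))) / ssx
    return slope.reshape(-1, 2)


def group_mean_shapes(tangent: np.ndarray, labels: Sequence,
                      consensus: np.ndarray,
                      magnification: float = 1.0) -> dict[str, np.ndarray]:
    """Per-group mean configurations back-projected from tangent space.

    With ``magnification`` > 1 the displacement of each group mean from the
    consensus is amplified for display (shape differences are typically a
    few percent of centroid size and hard to see at natural scale).
    """
    y = np.atleast_2d(np.asarray(tangent, dtype=float))
    lab = np.asarray(labels).astype(str)
    cons = np.asarray(consensus, dtype=float)
    out = {}
    for g in sorted(np.unique(lab)):
        mean_t = y[lab == g].mean(axis=0).reshape(cons.shape)
        out[g] = cons + magnification * mean_t
    return out


def boxplot_stats(values: Sequence[float], labels: Sequence) -> pd.DataFrame:
    """Per-group summaries: mean line, quartile box, 5th/95th whiskers.

    The centre line is the *mean* (not the median); box margins are the 25th
    and 75th percentiles and whiskers the 5th and 95th, all with the
    linear-interpolation percentile convention.  Values outside the whiskers
    are listed as outliers.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels).astype(str)
    rows = []
    for g in sorted(np.unique(lab)):
        x = v[lab == g]
        p5, p25, p75, p95 = np.percentile(x, [5, 25, 75, 95])
        rows.append({
            "group": g, "n": int(x.size), "mean": float(x.mean()),
            "p5": float(p5), "p25": float(p25),
            "p75": float(p75), "p95": float(p95),
            "outliers": [float(o) for o in x[(x < p5) | (x > p95)]],
        })
    return pd.DataFrame(rows)


def plot_size_boxes(values, labels, path, title="Centroid size"):
    """Render the centroid-size box plot (mean line, 25/75 box, 5/95 bars)."""
    stats = boxplot_stats(values, labels)
    fig, ax = plt.subplots(figsize=(1.2 * len(stats) + 2, 4))
    for i, row in stats.iterrows():
        ax.add_patch(plt.Rectangle((i - 0.3, row.p25), 0.6,
                                   row.p75 - row.p25,
                                   fill=False, edgecolor="black"))
        ax.hlines(row["mean"], i - 0.3, i + 0.3, color="black", lw=2)
        ax.vlines(i, row.p75, row.p95, color="black")
        ax.vlines(i, row.p5, row.p25, color="black")
        if row.outliers:
            ax.plot([i] * len(row.outliers), row.outliers, "o",
                    mfc="none", mec="black", ms=4)
    ax.set_xticks(range(len(stats)))
    ax.set_xticklabels(stats.group)
    ax.set_ylabel(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return stats


def plot_scores_scatter(scores, labels, path, axis_names=("axis 1", "axis 2"),
                        var_explained=None):
    """Scatter of the first two ordination axes, one marker set per group."""
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    lab = np.asarray(labels).astype(str)
    fig, ax = plt.subplots(figsize=(5, 5))
    for g, marker in zip(sorted(np.unique(lab)), "osD^v<>*"):
        sel = lab == g
        ax.scatter(x[sel, 0], x[sel, 1], label=g, marker=marker, alpha=0.8)
    names = list(axis_names)
    if var_explained is not None:
        names = [f"{n} ({100 * v:.1f}%)"
                 for n, v in zip(names, var_explained)]
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_deformation(consensus, shapes: dict[str, np.ndarray], path,
                     links: Sequence[tuple[int, int]] = ()):
    """Overlay group mean configurations on the consensus.

    ``links`` is an optional user-supplied wireframe (0-based landmark index
    pairs) joined by lines for each shape.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    cons = np.asarray(consensus, dtype=float)
    ax.plot(cons[:, 0], cons[:, 1], ".", color="0.7", ms=4,
            label="consensus")
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for (g, shape), color in zip(sorted(shapes.items()), colors):
        s = np.asarray(shape)
        ax.plot(s[:, 0], s[:, 1], ".", color=color, ms=5, label=g)
        for a, b in links:
            ax.plot(s[[a, b], 0], s[[a, b], 1], "-", color=color, lw=0.8)
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
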