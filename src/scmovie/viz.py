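"""Publication-style figures; every plot also returns its statistics.

Forests are drawn radially (master root at the center, one sector per
colony, radius = tree level); scatter plots carry the least-squares
line/plane, Pearson r and optional density binning; group summaries
(violin, box, pdf overlay, per-time dots) share a common y-axis so groups
can be compared.  Layouts and palettes are deterministic: children are
ordered by cell id and colony/generation colors are stable hash-based
mappings, so the same dataset renders identically across figures and
runs.  Tests assert on the returned numbers, not on pixels.
"""

from __future__ import annotations

import hashlib
import math

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as sps

from .lineage_forest import MASTER, is_synthetic
from .stochasticity import fit_distribution

_PALETTE = plt.get_cmap("tab20").colors


def stable_color(label) -> tuple:
    """Deterministic color for a colony/generation label."""
    h = int(hashlib.sha1(str(label).encode()).hexdigest()[:8], 16)
    return _PALETTE[h % len(_PALETTE)]


def _save(fig, out, width: float, height: float, dpi: int):
    fig.set_size_inches(width, height)
    fig.savefig(out, dpi=dpi)
    plt.close(fig)


def _radial_layout(forest) -> dict:
    """Radial positions: radius = level - 1, leaves at equal angles.

    Children are visited in sorted order, so the layout is a pure
    function of the forest.
    """
    graph = forest.graph
    pos = {MASTER: (0.0, 0.0)}
    leaves = [n for n in graph.nodes if graph.out_degree(n) == 0]
    n_leaves = max(len(leaves), 1)
    angle_of: dict = {}
    next_slot = [0]

    def visit(node):
        kids = sorted(graph.successors(node), key=str)
        if not kids:
            angle_of[node] = 2 * math.pi * next_slot[0] / n_leaves
            next_slot[0] += 1
        else:
            for k in kids:
                visit(k)
            angle_of[node] = sum(angle_of[k] for k in kids) / len(kids)

    visit(MASTER)
    for n in graph.nodes:
        r = forest.level(n) - 1
        a = angle_of.get(n, 0.0)
        pos[n] = (r * math.cos(a), r * math.sin(a))
    return pos


def plot_forest(
    forest,
    attr: str,
    out,
    width: float = 8.0,
    height: float = 8.0,
    dpi: int = 150,
) -> dict:
    """Draw a forest with an attribute colormapped onto the nodes.

    ``attr`` may be a numeric instance/life attribute (continuous
    colormap with a colorbar) or a categorical label such as ``colony``
    or ``generation`` (stable per-label hues).  Synthetic root nodes are
    uncolored.  Returns layout/statistics metadata.
    """
    nodes = [n for n in forest.graph.nodes if not is_synthetic(n)]
    if not nodes:
        raise ValueError("forest has no cell nodes")
    missing = [n for n in nodes if attr not in forest.graph.nodes[n]]
    if missing:
        raise KeyError(f"attribute {attr!r} missing on {len(missing)} nodes")
    values = [forest.graph.nodes[n][attr] for n in nodes]
    pos = _radial_layout(forest)

    fig, ax = plt.subplots()
    for a, b in forest.graph.edges:
        xa, ya = pos[a]
        xb, yb = pos[b]
        ax.plot([xa, xb], [ya, yb], color="0.8", lw=0.5, zorder=1)
    sx = [pos[n][0] for n in nodes]
    sy = [pos[n][1] for n in nodes]
    categorical = attr in ("colony", "generation") or not isinstance(values[0], (int, float))
    if categorical:
        colors = [stable_color(v) for v in values]
        ax.scatter(sx, sy, c=colors, s=12, zorder=2)
    else:
        sc = ax.scatter(sx, sy, c=values, s=12, cmap="viridis", zorder=2)
        fig.colorbar(sc, ax=ax, label=attr)
    syn = [n for n in forest.graph.nodes if is_synthetic(n)]
    ax.scatter([pos[n][0] for n in syn], [pos[n][1] for n in syn],
               facecolors="none", edgecolors="0.5", s=20, zorder=2)
    ax.set_aspect("equal")
    ax.set_axis_off()
    _save(fig, out, width, height, dpi)
    return {
        "n_nodes": len(nodes),
        "n_levels": len({forest.level(n) for n in forest.graph.nodes}),
        "categorical": categorical,
    }


def plot_scatter(
    x,
    y,
    out=None,
    color_by=None,
    density_bins: int | None = None,
    regression: bool = True,
    diagonal: bool = False,
    width: float = 6.0,
    height: float = 5.0,
    dpi: int = 150,
    labels: tuple[str, str] = ("x", "y"),
) -> dict:
    """XY scatter with least-squares line, Pearson r, optional density bins.

    Returns slope, intercept, R², and Pearson r of the plotted data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    reg = sps.linregress(x, y)
    r = float(sps.pearsonr(x, y).statistic)
    stats = {
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "r_squared": r * r,
        "pearson_r": r,
        "n": int(x.size),
    }
    if out is not None:
        fig, ax = plt.subplots()
        if density_bins:
            h = ax.hist2d(x, y, bins=density_bins, cmap="viridis", cmin=1)
            fig.colorbar(h[3], ax=ax, label="count")
        elif color_by is not None:
            ax.scatter(x, y, c=[stable_color(v) for v in color_by], s=10)
        else:
            ax.scatter(x, y, s=10)
        xs = np.array([x.min(), x.max()])
        if regression:
            ax.plot(xs, reg.intercept + reg.slope * xs, "k-", lw=1.5)
        if diagonal:
            ax.plot([x.min(), x.max()], [y.min(), y.max()], color="0.6", lw=1)
        ax.set_xlabel(labels[0])
        ax.set_ylabel(labels[1])
        _save(fig, out, width, height, dpi)
    return stats


def plot_scatter3(
    x, y, z, out=None, width: float = 6.0, height: float = 5.0, dpi: int = 150
) -> dict:
    """XYZ scatter with the least-squares plane z = a x + b y + c.

    Returns (a, b, c) and R².  Collinear predictors produce the
    minimum-norm solution with a rank-deficiency warning in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 points, got {x.size}")
    A = np.column_stack([x, y, np.ones_like(x)])
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    pred = A @ coef
    ss_res = float(np.sum((z - pred) ** 2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    stats = {
        "a": float(coef[0]),
        "b": float(coef[1]),
        "c": float(coef[2]),
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan,
        "rank_deficient": rank < 3,
        "n": int(x.size),
    }
    if out is not None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
        ax.scatter(x, y, z, s=10)
        gx, gy = np.meshgrid(
            np.linspace(x.min(), x.max(), 10), np.linspace(y.min(), y.max(), 10)
        )
        ax.plot_surface(gx, gy, coef[0] * gx + coef[1] * gy + coef[2], alpha=0.3)
        _save(fig, out, width, height, dpi)
    return stats


def plot_group_summaries(
    values_by_group: dict,
    kind: str = "violin",
    out=None,
    family: str | None = None,
    width: float = 7.0,
    height: float = 5.0,
    dpi: int = 150,
    ylabel: str = "",
) -> dict:
    """Violin / box / pdf-overlay / per-time dot plots with a shared axis.

    ``values_by_group`` maps group label -> samples.  ``pdf_overlay``
    additionally fits ``family`` (default normal) per group and overlays
    the fitted density on the histogram.  Returns per-group means, sds,
    counts (and fitted parameters for pdf_overlay); empty groups are
    skipped.
    """
    if kind not in ("violin", "box", "pdf_overlay", "time_dots"):
        raise ValueError(f"unknown kind {kind!r}")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items() if len(v)}
    if not groups:
        raise ValueError("all groups are empty")
    keys = sorted(groups, key=str)
    stats = {
        k: {"mean": float(groups[k].mean()), "sd": float(groups[k].std(ddof=1)) if groups[k].size > 1 else 0.0,
            "n": int(groups[k].size)}
        for k in keys
    }

    if out is not None:
        fig, ax = plt.subplots()
        data = [groups[k] for k in keys]
        colors = [stable_color(k) for k in keys]
        if kind in ("violin", "box"):
            if kind == "violin":
                parts = ax.violinplot(data, showmedians=True)
                for body, c in zip(parts["bodies"], colors):
                    body.set_facecolor(c)
            else:
                ax.boxplot(data)
            ax.set_xticks(range(1, len(keys) + 1), [str(k) for k in keys])
        elif kind == "time_dots":
            for i, k in enumerate(keys):
                ax.plot(np.full(groups[k].size, i + 1), groups[k], ".", ms=3, color=colors[i])
            ax.set_xticks(range(1, len(keys) + 1), [str(k) for k in keys])
        else:  # pdf_overlay
            fam = family or "normal"
            for k, c in zip(keys, colors):
                v = groups[k]
                ax.hist(v, bins=30, density=True, alpha=0.3, color=c)
                fit = fit_distribution(v, fam)
                xs = np.linspace(v.min(), v.max(), 200)
                if fam == "normal":
                    pdf = sps.norm.pdf(xs, *fit.params)
                elif fam == "gamma":
                    pdf = sps.gamma.pdf(xs, a=fit.params[0], scale=1 / fit.params[1])
                else:
                    pdf = sps.lognorm.pdf(xs, s=fit.params[1], scale=math.exp(fit.params[0]))
                ax.plot(xs, pdf, color=c, lw=1.5)
                stats[k]["fit_family"] = fam
                stats[k]["fit_params"] = fit.params
        lo = min(g.min() for g in groups.values())
        hi = max(g.max() for g in groups.values())
        pad = 0.05 * (hi - lo) if hi > lo else 1.0
        ax.set_ylim(lo - pad, hi + pad)
        ax.set_ylabel(ylabel)
        _save(fig, out, width, height, dpi)
    return stats
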