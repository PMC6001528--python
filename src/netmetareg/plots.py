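"""The five covariate/contribution diagnostic graphs.

All functions write figure files (png/svg/pdf) and return the paths written.
Layouts are deterministic given the inputs and style: nodes sit on a fixed
circle, colours and scalings come from :class:`PlotStyle`.

Graph types:

* network covariate distribution diagram — the evidence network with a
  histogram of covariate values per direct-comparison edge (inline for small
  networks, as a side panel grid otherwise);
* covariate-contribution plot — per NMR result (or per comparison), each
  study's percentage contribution against its covariate value;
* heat plot — results x covariate-bin matrix of summed contributions with
  colour shading and numeric annotation;
* contribution-NMR plot — per comparison, the regression line with its 95%
  band, direct-evidence trials plotted at their observed effects and
  indirect-evidence trials along the top, circle areas scaled to the
  contributions (red = effect, blue = coefficient);
* heat-NMR plot — the same line and band with the band's upper half coloured
  by the binned effect contributions and the lower half by the binned
  coefficient contributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .contributions import BinSpec, ContributionTable, ResultSpec
from .data_io import ContrastDataset, NetworkSummary
from .model import FitResult, predict_effect

__all__ = [
    "PlotStyle",
    "plot_network_covariate",
    "plot_covariate_contribution",
    "plot_heat",
    "plot_contribution_nmr",
    "plot_heat_nmr",
]


@dataclass(frozen=True)
class PlotStyle:
    """Colours, scalings and output format shared by all graph types."""

    effect_color: str = "red"
    coefficient_color: str = "blue"
    heat_cmap: str = "coolwarm"  # blue -> red ramp
    circle_divisor: float = 1.0
    hist_bin_width: float | None = None
    fmt: str = "png"
    dpi: int = 120

    def __post_init__(self) -> None:
        if self.circle_divisor <= 0:
            raise ValueError("circle divisor must be > 0")
        if self.fmt not in ("png", "svg", "pdf"):
            raise ValueError("format must be png, svg or pdf")


def _outpath(out, name: str, style: PlotStyle) -> Path:
    out = Path(out)
    if out.suffix:  # explicit file path
        return out
    out.mkdir(parents=True, exist_ok=True)
    return out / f"{name}.{style.fmt}"


def _save(fig, path: Path, style: PlotStyle) -> Path:
    fig.savefig(path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def _circle_positions(nodes: Sequence[str]) -> dict[str, np.ndarray]:
    n = len(nodes)
    return {
        t: np.array([math.cos(2 * math.pi * i / n + math.pi / 2),
                     math.sin(2 * math.pi * i / n + math.pi / 2)])
        for i, t in enumerate(nodes)
    }


def _edge_covariates(data: ContrastDataset) -> dict[tuple[str, str], list[float]]:
    import itertools

    out: dict[tuple[str, str], list[float]] = {}
    for s in data.studies:
        arms = sorted([s.baseline] + s.treatments)
        for pair in itertools.combinations(arms, 2):
            out.setdefault(pair, []).append(s.covariate + data.covariate_center)
    return out


def _hist_bins(values: Sequence[float], style: PlotStyle) -> np.ndarray | str:
    if style.hist_bin_width is None:
        return "auto"
    lo = math.floor(min(values) / style.hist_bin_width) * style.hist_bin_width
    hi = math.ceil(max(values) / style.hist_bin_width) * style.hist_bin_width
    return np.arange(lo, hi + style.hist_bin_width, style.hist_bin_width)


def plot_network_covariate(
    net: NetworkSummary,
    data: ContrastDataset,
    out,
    style: PlotStyle = PlotStyle(),
    layout: str = "inline_histograms",
) -> Path:
    """Evidence network with per-edge covariate histograms."""
    if layout not in ("inline_histograms", "side_histograms"):
        raise ValueError("layout must be 'inline_histograms' or 'side_histograms'")
    if layout == "inline_histograms" and len(net.treatments) > 4:
        warnings.warn(
            "inline histograms become cluttered beyond 4 treatments; "
            "consider layout='side_histograms'",
            UserWarning,
            stacklevel=2,
        )
    pos = _circle_positions(net.treatments)
    edge_covs = _edge_covariates(data)

    if layout == "inline_histograms":
        fig, ax = plt.subplots(figsize=(7, 7))
        ax.set_xlim(-1.6, 1.6)
        ax.set_ylim(-1.6, 1.6)
        ax.set_aspect("equal")
        ax.axis("off")
        for (pair, count) in net.edges:
            p1, p2 = pos[pair[0]], pos[pair[1]]
            ax.plot(*zip(p1, p2), color="0.6", zorder=1)
            mid = (p1 + p2) / 2
            ax.annotate(
                str(count), mid + 0.08, ha="center", fontsize=9, color="0.3"
            )
            inset = ax.inset_axes(
                [mid[0] * 0.42 + 0.5 - 0.11, mid[1] * 0.42 + 0.5 - 0.055, 0.22, 0.11],
                transform=ax.transAxes,
            )
            inset.hist(edge_covs[pair], bins=_hist_bins(edge_covs[pair], style),
                       color="0.4")
            inset.set_yticks([])
            inset.tick_params(labelsize=5)
        for t, p in pos.items():
            ax.scatter(*p, s=600, color="white", edgecolor="black", zorder=3)
            ax.annotate(t, p, ha="center", va="center", zorder=4)
        path = _outpath(out, "network_covariate", style)
        return _save(fig, path, style)

    n_edges = len(net.edges)
    ncols = min(3, n_edges)
    nrows = math.ceil(n_edges / ncols)
    fig = plt.figure(figsize=(4 + 3 * ncols, max(4, 2.2 * nrows)))
    gs = fig.add_gridspec(1, 2, width_ratios=[1.2, ncols])
    ax_net = fig.add_subplot(gs[0, 0])
    ax_net.set_aspect("equal")
    ax_net.axis("off")
    for (pair, count) in net.edges:
        p1, p2 = pos[pair[0]], pos[pair[1]]
        ax_net.plot(*zip(p1, p2), color="0.6", zorder=1)
        mid = (p1 + p2) / 2
        ax_net.annotate(str(count), mid, ha="center", fontsize=8, color="0.3")
    for t, p in pos.items():
        ax_net.scatter(*p, s=500, color="white", edgecolor="black", zorder=3)
        ax_net.annotate(t, p, ha="center", va="center", zorder=4)
    sub = gs[0, 1].subgridspec(nrows, ncols)
    for j, (pair, _count) in enumerate(net.edges):
        axh = fig.add_subplot(sub[j // ncols, j % ncols])
        axh.hist(edge_covs[pair], bins=_hist_bins(edge_covs[pair], style), color="0.4")
        axh.set_title(f"{pair[0]} vs {pair[1]}", fontsize=8)
        axh.tick_params(labelsize=7)
    path = _outpath(out, "network_covariate", style)
    return _save(fig, path, style)


def _comparisons_of(table: ContributionTable) -> list[tuple[str, str]]:
    comps = []
    for label in table.values.index:
        body = label.split(":", 1)[1].split("@", 1)[0]
        a, b = body.split("_vs_")
        if (a, b) not in comps:
            comps.append((a, b))
    return comps


def _result_label(kind: str, comp: tuple[str, str]) -> str:
    return (f"d:{comp[0]}_vs_{comp[1]}@center" if kind == "effect"
            else f"beta:{comp[0]}_vs_{comp[1]}")


def plot_covariate_contribution(
    table: ContributionTable,
    data: ContrastDataset,
    out,
    style: PlotStyle = PlotStyle(),
    mode: str = "one_graph_per_result",
) -> Path:
    """Study contribution (%) against covariate value, one panel per result
    (study numbers as glyphs) or per comparison (red/blue point pairs)."""
    if table.level != "study":
        raise ValueError("expects a study-level contribution table")
    covs = data.covariates(original_scale=True)
    study_order = [s.study_id for s in data.studies]
    numbers = {sid: i + 1 for i, sid in enumerate(study_order)}

    if mode == "one_graph_per_result":
        labels = list(table.values.index)
        ncols = 2
        nrows = math.ceil(len(labels) / ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(9, 2.8 * nrows), squeeze=False)
        for j, label in enumerate(labels):
            ax = axes[j // ncols][j % ncols]
            for sid in table.data_columns:
                ax.annotate(
                    str(numbers[sid]),
                    (covs[sid], table.values.loc[label, sid]),
                    ha="center", va="center", fontsize=8,
                )
            ax.set_xlim(min(covs.values()) - 1, max(covs.values()) + 1)
            ax.set_ylim(-3, max(103, table.values.loc[label].max() + 5))
            ax.set_title(label, fontsize=9)
            ax.set_xlabel("covariate")
            ax.set_ylabel("contribution (%)")
        for j in range(len(labels), nrows * ncols):
            axes[j // ncols][j % ncols].axis("off")
    elif mode == "one_graph_per_comparison":
        comps = _comparisons_of(table)
        ncols = 3
        nrows = math.ceil(len(comps) / ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(12, 2.8 * nrows), squeeze=False)
        for j, comp in enumerate(comps):
            ax = axes[j // ncols][j % ncols]
            eff = _result_label("effect", comp)
            coe = _result_label("coefficient", comp)
            x = [covs[sid] for sid in table.data_columns]
            if eff in table.values.index:
                ax.scatter(x, table.values.loc[eff, table.data_columns],
                           color=style.effect_color, s=14, label="effect")
            if coe in table.values.index:
                ax.scatter(x, table.values.loc[coe, table.data_columns],
                           color=style.coefficient_color, s=14, label="coefficient")
            ax.set_title(f"{comp[0]} vs {comp[1]}", fontsize=9)
            ax.set_xlabel("covariate")
            ax.set_ylabel("contribution (%)")
        for j in range(len(comps), nrows * ncols):
            axes[j // ncols][j % ncols].axis("off")
        axes[0][0].legend(fontsize=7)
    else:
        raise ValueError("mode must be 'one_graph_per_result' or 'one_graph_per_comparison'")
    fig.tight_layout()
    path = _outpath(out, "covariate_contribution", style)
    return _save(fig, path, style)


def plot_heat(
    binned: ContributionTable, out, style: PlotStyle = PlotStyle()
) -> Path:
    """Results x covariate-bin matrix, colour-shaded with integer annotations."""
    if binned.level != "bin":
        raise ValueError("expects a bin-level contribution table")
    mat = binned.values[binned.data_columns].to_numpy()
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.75 * mat.shape[1], 1.0 + 0.45 * mat.shape[0])
    )
    vmax = mat.max() if mat.max() > 0 else 1.0
    masked = np.ma.masked_where(mat == 0, mat)
    cmap = plt.get_cmap(style.heat_cmap).copy()
    cmap.set_bad("white")
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=vmax, aspect="auto")
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            if mat[i, j] > 0:
                ax.annotate(
                    f"{mat[i, j]:.0f}", (j, i), ha="center", va="center", fontsize=7
                )
    ax.set_xticks(range(mat.shape[1]), binned.data_columns, rotation=45, ha="right",
                  fontsize=7)
    ax.set_yticks(range(mat.shape[0]), binned.values.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="contribution (%)")
    path = _outpath(out, "heat", style)
    return _save(fig, path, style)


def _direct_indirect(data: ContrastDataset, comp: tuple[str, str]):
    """Split studies into direct (randomise both arms) and the rest."""
    direct, indirect = [], []
    for s in data.studies:
        arms = {s.baseline, *s.treatments}
        (direct if comp[0] in arms and comp[1] in arms else indirect).append(s)
    return direct, indirect


def _observed_effect(s, comp: tuple[str, str]) -> float:
    """Observed contrast of comp[0] vs comp[1] within one direct study."""
    arms = [s.baseline] + list(s.treatments)
    eff = {t: 0.0 for t in arms}
    for j, t in enumerate(s.treatments):
        eff[t] = float(s.y[j])
    return eff[comp[0]] - eff[comp[1]]


def _grid(data: ContrastDataset, n: int = 100) -> np.ndarray:
    covs = list(data.covariates(original_scale=True).values())
    return np.linspace(min(covs), max(covs), n)


def plot_contribution_nmr(
    fit: FitResult,
    table: ContributionTable,
    data: ContrastDataset,
    out,
    style: PlotStyle = PlotStyle(),
    show_contributions: bool = True,
) -> Path:
    """Regression line + band per comparison, trials as contribution-scaled circles.

    Direct-evidence trials sit in the bottom section at (covariate, observed
    effect); indirect-evidence trials sit in the top strip at their covariate
    (they have no observed effect for this comparison).  Circle *areas* are
    proportional to contribution divided by the style divisor; red circles for
    the effect, blue for the coefficient.  ``show_contributions=False`` plots
    uniform-size points instead.
    """
    if table.level != "study":
        raise ValueError("expects a study-level contribution table")
    comps = _comparisons_of(table)
    covs = data.covariates(original_scale=True)
    grid = _grid(data)
    ncols = min(3, len(comps))
    nrows = math.ceil(len(comps) / ncols)
    fig = plt.figure(figsize=(4.2 * ncols, 3.6 * nrows))
    outer = fig.add_gridspec(nrows, ncols, hspace=0.45)

    def sizes(label, sids):
        if not show_contributions or label not in table.values.index:
            return np.full(len(sids), 30.0)
        return 20.0 * table.values.loc[label, sids].to_numpy() / style.circle_divisor

    for j, comp in enumerate(comps):
        sub = outer[j // ncols, j % ncols].subgridspec(
            2, 1, height_ratios=[1, 4], hspace=0.08
        )
        ax_top = fig.add_subplot(sub[0, 0])
        ax_bot = fig.add_subplot(sub[1, 0], sharex=ax_top)

        est_lo_hi = [predict_effect(fit, comp, x) for x in grid]
        est = np.array([e for e, _ in est_lo_hi])
        lo = np.array([l for _, (l, _) in est_lo_hi])
        hi = np.array([h for _, (_, h) in est_lo_hi])
        ax_bot.plot(grid, est, color="black", lw=1.6, dashes=[6, 2, 1, 2])
        ax_bot.plot(grid, lo, color="black", lw=0.8, ls="--")
        ax_bot.plot(grid, hi, color="black", lw=0.8, ls="--")

        direct, indirect = _direct_indirect(data, comp)
        eff_label = _result_label("effect", comp)
        coe_label = _result_label("coefficient", comp)
        if direct:
            sids = [s.study_id for s in direct]
            x = [covs[sid] for sid in sids]
            yobs = [_observed_effect(s, comp) for s in direct]
            ax_bot.scatter(x, yobs, s=sizes(eff_label, sids),
                           facecolors="none", edgecolors=style.effect_color)
            ax_bot.scatter(x, yobs, s=sizes(coe_label, sids),
                           facecolors="none", edgecolors=style.coefficient_color)
        if indirect:
            sids = [s.study_id for s in indirect]
            x = [covs[sid] for sid in sids]
            y0 = np.zeros(len(x))
            ax_top.scatter(x, y0, s=sizes(eff_label, sids),
                           facecolors="none", edgecolors=style.effect_color)
            ax_top.scatter(x, y0, s=sizes(coe_label, sids),
                           facecolors="none", edgecolors=style.coefficient_color)
        ax_top.set_yticks([])
        ax_top.set_ylim(-1, 1)
        ax_top.set_title(f"{comp[0]} vs {comp[1]}", fontsize=9)
        plt.setp(ax_top.get_xticklabels(), visible=False)
        ax_bot.set_xlabel("covariate")
        ax_bot.set_ylabel("effect")
    path = _outpath(out, "contribution_nmr", style)
    return _save(fig, path, style)


def plot_heat_nmr(
    fit: FitResult,
    binned: ContributionTable,
    out,
    style: PlotStyle = PlotStyle(),
    grid_n: int = 100,
) -> Path:
    """Regression line + band per comparison with the band colour-shaded by bin.

    The half of the band above the line is coloured by the binned effect
    contributions, the half below by the binned coefficient contributions,
    using the heat-plot ramp.
    """
    if binned.level != "bin":
        raise ValueError("expects a bin-level contribution table")
    comps = _comparisons_of(binned)
    bin_labels = binned.data_columns
    edges = []
    for lab in bin_labels:
        lo, hi = lab.split("–")
        edges.append((float(lo), float(hi)))
    vmax = binned.values[bin_labels].to_numpy().max()
    vmax = vmax if vmax > 0 else 1.0
    cmap = plt.get_cmap(style.heat_cmap)

    ncols = min(3, len(comps))
    nrows = math.ceil(len(comps) / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows),
                             squeeze=False)
    lo_all = min(lo for lo, _ in edges)
    hi_all = max(hi for _, hi in edges)
    grid = np.linspace(lo_all, hi_all, grid_n)
    for j, comp in enumerate(comps):
        ax = axes[j // ncols][j % ncols]
        est_lo_hi = [predict_effect(fit, comp, x) for x in grid]
        est = np.array([e for e, _ in est_lo_hi])
        lo = np.array([l for _, (l, _) in est_lo_hi])
        hi = np.array([h for _, (_, h) in est_lo_hi])
        eff_label = _result_label("effect", comp)
        coe_label = _result_label("coefficient", comp)
        for lab, (blo, bhi) in zip(bin_labels, edges):
            mask = (grid >= blo) & (grid <= bhi)
            if not mask.any():
                continue
            if eff_label in binned.values.index:
                val = binned.values.loc[eff_label, lab]
                ax.fill_between(grid[mask], est[mask], hi[mask],
                                color=cmap(val / vmax), linewidth=0)
            if coe_label in binned.values.index:
                val = binned.values.loc[coe_label, lab]
                ax.fill_between(grid[mask], lo[mask], est[mask],
                                color=cmap(val / vmax), linewidth=0)
        ax.plot(grid, est, color="black", lw=1.6, dashes=[6, 2, 1, 2])
        ax.plot(grid, lo, color="black", lw=0.8, ls="--")
        ax.plot(grid, hi, color="black", lw=0.8, ls="--")
        ax.set_title(f"{comp[0]} vs {comp[1]}", fontsize=9)
        ax.set_xlabel("covariate")
        ax.set_ylabel("effect")
    for j in range(len(comps), nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    path = _outpath(out, "heat_nmr", style)
    return _save(fig, path, style)
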