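"""Two-panel balance visualization.

Instead of embedding one box plot per balance inside a dendrogram — each
with its own sporadic scale — the balances are laid out as rows shared by
two aligned panels: the left (contrast) panel shows which components enter
each balance on the "+" or the "-" side, and the right (distribution) panel
shows every sample's score for each balance on one common value axis, with
a horizontal segment spanning the score range (its thickness can encode the
proportion of total variance explained). The common scale makes balances
directly comparable, and any subset of rows can be shown without changing
the meaning of the rest.

Correctness lives in :class:`BalancePlotSpec`, a renderer-independent data
model; rendering is a thin matplotlib layer on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .balances import compute_balances, subset_balances
from .core import AlignmentError, CompositionTable, DomainError
from .sbp import SbpMatrix, order_balances

__all__ = ["PlotOptions", "BalancePlotSpec", "build_plot_spec", "render",
           "write_spec_tsv"]


@dataclass(frozen=True)
class PlotOptions:
    show_width_by_variance: bool = False
    boxplot_split: bool = False
    text_size: float = 10.0
    point_size: float = 20.0


@dataclass(frozen=True)
class BalancePlotSpec:
    """Renderer-independent description of the two-panel figure.

    ``balance_ids`` fixes the shared row order (base of the tree at the
    top); ``scale`` is the single global (min, max) of all scores shown, so
    every row of the distribution panel lives on one common axis. Summary
    proportions always come from the full D-1 decomposition, even when only
    a subset of balances is displayed.
    """

    balance_ids: tuple
    contrast_records: pd.DataFrame   # balance_id, component_id, side, component_group
    distribution_records: pd.DataFrame  # balance_id, sample_id, score, sample_group
    summary: pd.DataFrame            # index balance_id: min, max, median, proportion
    scale: tuple
    options: PlotOptions = field(default_factory=PlotOptions)


def _as_group_series(group, index, what: str) -> pd.Series:
    index = pd.Index(index)
    if isinstance(group, pd.Series):
        missing = index.difference(group.index)
        if len(missing):
            raise AlignmentError(
                f"{what} group labels missing for: {list(missing)[:5]}"
            )
        return group.reindex(index)
    group = list(group)
    if len(group) != len(index):
        raise AlignmentError(
            f"{what} group vector has length {len(group)}, "
            f"expected {len(index)}"
        )
    return pd.Series(group, index=index)


def build_plot_spec(data: CompositionTable, sbp: SbpMatrix,
                    selected=None, d_group=None, n_group=None,
                    options: PlotOptions | None = None) -> BalancePlotSpec:
    """Assemble the plot spec for a composition table and SBP.

    ``selected`` restricts the rows shown (default: all balances); scores
    and summaries of the selected balances are identical to their values in
    the full computation. ``d_group`` labels components, ``n_group`` labels
    samples; each must cover every component/sample.
    """
    options = options or PlotOptions()
    full = compute_balances(data, sbp)
    if selected is None:
        selected = full.balance_ids
    selected = list(selected)
    if not selected:
        raise DomainError("selection of balances must be non-empty")
    shown = subset_balances(full, selected)
    ordered = order_balances(sbp, selected, full.summary["variance"])

    dg = (_as_group_series(d_group, data.component_ids, "component")
          if d_group is not None else None)
    ng = (_as_group_series(n_group, data.sample_ids, "sample")
          if n_group is not None else None)

    contrast_rows = []
    for b in ordered:
        for side, members in (("plus", sorted(sbp.plus_set(b))),
                              ("minus", sorted(sbp.minus_set(b)))):
            for comp in members:
                contrast_rows.append({
                    "balance_id": b, "component_id": comp, "side": side,
                    "component_group": dg[comp] if dg is not None else None,
                })
    contrast = pd.DataFrame(
        contrast_rows,
        columns=["balance_id", "component_id", "side", "component_group"])

    dist_rows = []
    for b in ordered:
        col = shown.scores[b]
        for sample_id, score in col.items():
            dist_rows.append({
                "balance_id": b, "sample_id": sample_id,
                "score": float(score),
                "sample_group": ng[sample_id] if ng is not None else None,
            })
    dist = pd.DataFrame(
        dist_rows, columns=["balance_id", "sample_id", "score", "sample_group"])

    summary = shown.summary.loc[
        ordered, ["min", "max", "median", "proportion_of_total_variance"]]
    scale = (float(dist["score"].min()), float(dist["score"].max()))
    return BalancePlotSpec(
        balance_ids=tuple(ordered),
        contrast_records=contrast,
        distribution_records=dist,
        summary=summary,
        scale=scale,
        options=options,
    )


def write_spec_tsv(spec: BalancePlotSpec, contrast_path, distribution_path) -> None:
    """Export the spec as a TSV pair for external plotting."""
    spec.contrast_records.to_csv(contrast_path, sep="\t", index=False)
    spec.distribution_records.to_csv(distribution_path, sep="\t", index=False)


def _group_palette(labels):
    uniq = sorted(pd.unique(labels))
    cmap = plt.get_cmap("tab10")
    return {g: cmap(i % 10) for i, g in enumerate(uniq)}


def render(spec: BalancePlotSpec, path, format: str = "svg"):
    """Render the two aligned panels to an SVG or PNG file."""
    if format not in ("svg", "png"):
        raise DomainError(f"format must be 'svg' or 'png', got {format!r}")
    opts = spec.options
    rows = list(spec.balance_ids)
    n_rows = len(rows)
    ypos = {b: n_rows - 1 - i for i, b in enumerate(rows)}  # top row first

    comps = list(pd.unique(spec.contrast_records["component_id"]))
    xpos = {c: i for i, c in enumerate(comps)}

    fig, (ax_l, ax_r) = plt.subplots(
        1, 2, sharey=True,
        figsize=(max(6.0, 0.22 * len(comps)) + 5.0, max(2.5, 0.45 * n_rows)),
        gridspec_kw={"width_ratios": [1.1, 1.0]},
    )

    # --- contrast panel -------------------------------------------------
    dgroups = spec.contrast_records["component_group"]
    dpal = _group_palette(dgroups.dropna()) if dgroups.notna().any() else None
    for _, rec in spec.contrast_records.iterrows():
        color = (dpal[rec["component_group"]]
                 if dpal is not None and pd.notna(rec["component_group"])
                 else "0.25")
        marker = "^" if rec["side"] == "plus" else "v"
        face = color if rec["side"] == "plus" else "none"
        ax_l.scatter(xpos[rec["component_id"]], ypos[rec["balance_id"]],
                     marker=marker, s=opts.point_size * 2.0,
                     facecolors=face, edgecolors=color, linewidths=0.8)
    ax_l.set_xticks(range(len(comps)))
    ax_l.set_xticklabels(comps, rotation=90, fontsize=opts.text_size * 0.7)
    ax_l.set_yticks(range(n_rows))
    ax_l.set_yticklabels([rows[n_rows - 1 - y] for y in range(n_rows)],
                         fontsize=opts.text_size * 0.8)
    ax_l.set_title("Balance contrasts (+ filled up / - open down)",
                   fontsize=opts.text_size)
    ax_l.set_xlim(-0.6, len(comps) - 0.4)

    # --- distribution panel --------------------------------------------
    ngroups = spec.distribution_records["sample_group"]
    npal = _group_palette(ngroups.dropna()) if ngroups.notna().any() else None
    prop = spec.summary["proportion_of_total_variance"]
    for b in rows:
        y = ypos[b]
        lw = (1.0 + 12.0 * float(prop[b])
              if opts.show_width_by_variance else 1.5)
        ax_r.hlines(y, spec.summary.loc[b, "min"], spec.summary.loc[b, "max"],
                    color="0.6", linewidth=lw, zorder=1)
        recs = spec.distribution_records[
            spec.distribution_records["balance_id"] == b]
        if opts.boxplot_split and npal is not None:
            groups = sorted(pd.unique(recs["sample_group"].dropna()))
            k = len(groups)
            for gi, g in enumerate(groups):
                scores = recs.loc[recs["sample_group"] == g, "score"]
                off = (gi - (k - 1) / 2.0) * (0.6 / max(k, 1))
                bp = ax_r.boxplot(
                    scores, positions=[y + off], orientation="horizontal",
                    widths=0.5 / k, patch_artist=True, manage_ticks=False,
                    showfliers=True, whis=1.5)
                for box in bp["boxes"]:
                    box.set_facecolor(npal[g])
                    box.set_alpha(0.45)
        colors = (recs["sample_group"].map(npal)
                  if npal is not None else "0.15")
        ax_r.scatter(recs["score"], np.full(len(recs), y),
                     s=opts.point_size, c=colors, alpha=0.65, zorder=2,
                     edgecolors="none")
    lo, hi = spec.scale
    pad = 0.05 * (hi - lo) if hi > lo else 0.5
    ax_r.set_xlim(lo - pad, hi + pad)
    ax_r.axvline(0.0, color="0.85", linewidth=0.8, zorder=0)
    ax_r.set_title("Sample distribution (common scale)",
                   fontsize=opts.text_size)
    ax_r.set_xlabel("balance score", fontsize=opts.text_size * 0.9)
    ax_l.set_ylim(-0.7, n_rows - 0.3)

    if npal is not None:
        handles = [plt.Line2D([], [], marker="o", linestyle="", color=c,
                              label=str(g)) for g, c in npal.items()]
        ax_r.legend(handles=handles, fontsize=opts.text_size * 0.7,
                    loc="best", title="samples")
    fig.tight_layout()
    fig.savefig(path, format=format)
    plt.close(fig)
    return path
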