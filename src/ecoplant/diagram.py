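"""Multi-panel stratigraphic pollen diagrams.

The rendering follows pollen-diagram convention: one panel per category,
panels side by side sharing a single vertical sample axis (optionally ordered
by depth, shallow at the top), one horizontal bar (or silhouette) per sample
per panel, percentages on the horizontal axes.  The Uncertain panel, when
present, is drawn last and greyed out so unlinked mass is visible but visually
separated from the interpretable signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
from matplotlib.figure import Figure

from .assemblage_io import AbundanceMatrix, read_wide_matrix
from .errors import ConfigurationError, ValidationError
from .reference import UNCERTAIN

__all__ = ["DiagramSpec", "render", "draw_curve"]

PAGE_FORMATS = ("pdf", "svg", "png")


@dataclass(frozen=True)
class DiagramSpec:
    """Rendering options for a pollen diagram.

    axis_order: "input_order" keeps the matrix's sample order (top to bottom);
        "by_depth" sorts samples by depth, shallowest on top, and requires a
        depth for every sample.
    panel_kind: "bars" (horizontal bars, the default) or "silhouette" (filled
        outline across samples).
    page_format: pdf (default), svg or png.
    scale_max: fixed horizontal-axis maximum for every panel, in percent;
        None scales each panel independently to its own maximum rounded up to
        the next multiple of 5 (set 100 to force full-scale panels).
    """

    axis_order: str = "input_order"
    panel_kind: str = "bars"
    page_format: str = "pdf"
    scale_max: float | None = None

    def __post_init__(self) -> None:
        if self.axis_order not in ("input_order", "by_depth"):
            raise ConfigurationError(f"unknown axis_order {self.axis_order!r}")
        if self.panel_kind not in ("bars", "silhouette"):
            raise ConfigurationError(f"unknown panel_kind {self.panel_kind!r}")
        if self.page_format.lower() not in PAGE_FORMATS:
            raise ConfigurationError(f"unknown page_format {self.page_format!r}")
        if self.scale_max is not None and self.scale_max <= 0:
            raise ConfigurationError("scale_max must be positive")


def _sample_order(matrix: AbundanceMatrix, spec: DiagramSpec) -> list[str]:
    if spec.axis_order == "input_order":
        return matrix.samples
    missing = [s for s in matrix.samples if s not in matrix.depths]
    if missing:
        raise ConfigurationError(
            "by_depth ordering requires a depth for every sample; missing: "
            + ", ".join(missing)
        )
    return sorted(matrix.samples, key=lambda s: matrix.depths[s])


def _panel_max(values: list[float], spec: DiagramSpec) -> float:
    if spec.scale_max is not None:
        return float(spec.scale_max)
    top = max(values) if values else 0.0
    return max(5.0, math.ceil(top / 5.0) * 5.0)


def render(
    matrix: AbundanceMatrix, spec: DiagramSpec = DiagramSpec(), sink=None
) -> Figure:
    """Render a percentage matrix as a pollen diagram; returns the Figure.

    One panel per category in matrix order, one track per sample in axis
    order.  The same matrix and spec always produce a structurally identical
    scene (panel count, track count, bar geometry), which is what the tests
    introspect.  When ``sink`` is given the figure is also written there in
    ``spec.page_format``.
    """
    if matrix.data.empty or not matrix.categories:
        raise ValidationError("cannot render an empty matrix")

    samples = _sample_order(matrix, spec)
    categories = matrix.categories
    n_panels = len(categories)
    n_tracks = len(samples)

    fig_w = max(4.0, 1.1 * n_panels + 1.6)
    fig_h = max(2.5, 0.45 * n_tracks + 1.8)
    fig, axes = plt.subplots(
        1, n_panels, sharey=True, figsize=(fig_w, fig_h), squeeze=False
    )
    axes = axes[0]

    # Track 0 at the top: invert by plotting at -index positions.
    positions = [-i for i in range(n_tracks)]
    for ax, category in zip(axes, categories):
        values = [matrix.value(s, category) for s in samples]
        colour = "0.55" if category == UNCERTAIN else "#3d6b35"
        if spec.panel_kind == "bars":
            ax.barh(positions, values, height=0.62, color=colour, gid=f"track:{category}")
        else:
            ax.fill_betweenx(
                positions, 0, values, color=colour, gid=f"track:{category}"
            )
            ax.plot(values, positions, color="black", linewidth=0.6)
        ax.set_xlim(0, _panel_max(values, spec))
        ax.set_title(category, rotation=45, ha="left", fontsize=8, style="italic")
        ax.tick_params(labelsize=7)
        ax.spines[["top", "right"]].set_visible(False)
        if category == UNCERTAIN:
            ax.set_facecolor("0.93")

    axes[0].set_yticks(positions, samples)
    axes[0].set_ylim(min(positions) - 0.6, 0.6)
    if spec.axis_order == "by_depth":
        axes[0].set_ylabel("Sample (by depth, shallow at top)", fontsize=8)
    fig.supxlabel("Abundance (%)", fontsize=8)
    fig.subplots_adjust(wspace=0.35, top=0.78, bottom=0.14, left=0.10, right=0.98)

    if sink is not None:
        fmt = spec.page_format.lower()
        path = Path(sink) if isinstance(sink, (str, Path)) else None
        if path is not None and path.suffix.lower().lstrip(".") in PAGE_FORMATS:
            fmt = path.suffix.lower().lstrip(".")
        fig.savefig(sink, format=fmt)
    return fig


def draw_curve(source, spec: DiagramSpec = DiagramSpec(), sink=None) -> Figure:
    """Plot a user-supplied wide matrix exactly as given.

    No reference lookup happens and no Uncertain column is added or removed:
    this is the mode for users who edited or combined result tables by hand
    and want them drawn verbatim.
    """
    matrix = read_wide_matrix(source)
    return render(matrix, spec, sink)
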