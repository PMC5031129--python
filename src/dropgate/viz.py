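"""Scatter-plot rendering of droplet clouds.

Follows the field's visual idiom: HEX (channel 2) on the x axis, FAM
(channel 1) on the y axis; empty droplets black, singly-positive orange,
double-positive green, rain blue. Empty droplets are hidden by default
since they dominate the counts and swamp the plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt

from .errors import SelectionError
from .wells import COLUMNS, ROWS, ClusterLabel

__all__ = ["PlotSpec", "render_well", "render_plate_grid", "DEFAULT_COLORS"]

DEFAULT_COLORS: dict[str, str] = {
    ClusterLabel.UNDEFINED.value: "#bbbbbb",
    ClusterLabel.FAILED.value: "#e8a0a0",
    ClusterLabel.OUTLIER.value: "#888888",
    ClusterLabel.EMPTY.value: "#000000",
    ClusterLabel.RAIN.value: "#1f77b4",
    ClusterLabel.SINGLE_POS.value: "#ff7f0e",
    ClusterLabel.DOUBLE_POS.value: "#2ca02c",
}


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options: colors per label, whether to show empty droplets
    and gate lines."""

    colors: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))
    show_empty: bool = False
    show_gates: bool = False
    point_size: float = 2.0
    dpi: int = 100

    def __post_init__(self) -> None:
        missing = [l.value for l in ClusterLabel if l.value not in self.colors]
        if missing:
            raise ValueError(f"no color for labels {missing}")


def _visible(df, spec: PlotSpec):
    hidden = set()
    if not spec.show_empty:
        hidden = {ClusterLabel.EMPTY.value, ClusterLabel.FAILED.value}
    return df[~df["label"].isin(hidden)]


def _scatter(ax, df, spec: PlotSpec) -> None:
    for label, sub in df.groupby("label", sort=True):
        ax.scatter(
            sub["ch2"],
            sub["ch1"],
            s=spec.point_size,
            c=spec.colors[str(label)],
            linewidths=0,
            rasterized=True,
        )


def _gate_lines(ax, row) -> None:
    import math

    g1, g2 = row.get("gate_ch1"), row.get("gate_ch2")
    if g1 is not None and isinstance(g1, float) and math.isfinite(g1):
        ax.axhline(g1, color="#666666", lw=0.8, ls="--")
    if g2 is not None and isinstance(g2, float) and math.isfinite(g2):
        ax.axvline(g2, color="#666666", lw=0.8, ls="--")


def render_well(plate, well: str, path, spec: PlotSpec | None = None):
    """Render one well's droplets to an image file (HEX vs FAM)."""
    spec = spec or PlotSpec()
    if well not in plate.plate_meta.index:
        raise SelectionError(f"well {well!r} not on this plate")
    df = _visible(plate.plate_data[plate.plate_data["well"] == well], spec)
    fig, ax = plt.subplots(figsize=(5, 4), dpi=spec.dpi)
    _scatter(ax, df, spec)
    if spec.show_gates:
        _gate_lines(ax, plate.plate_meta.loc[well])
    ax.set_xlabel("HEX amplitude (ch2)")
    ax.set_ylabel("FAM amplitude (ch1)")
    ax.set_title(f"{plate.name} {well}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def render_plate_grid(plate, path, spec: PlotSpec | None = None):
    """Render every well in plate geometry (rows A-H x columns 1-12) with
    shared axes; failed wells get a background tint, absent wells stay
    blank."""
    spec = spec or PlotSpec()
    data = _visible(plate.plate_data, spec)
    if len(data):
        xlim = (data["ch2"].min(), data["ch2"].max())
        ylim = (data["ch1"].min(), data["ch1"].max())
    else:
        xlim = ylim = (0, 1)

    fig, axes = plt.subplots(
        len(ROWS), len(COLUMNS), figsize=(16, 9), dpi=spec.dpi,
        sharex=True, sharey=True,
    )
    for i, r in enumerate(ROWS):
        for j, c in enumerate(COLUMNS):
            ax = axes[i, j]
            ax.set_xticks([])
            ax.set_yticks([])
            well = f"{r}{c:02d}"
            if well not in plate.plate_meta.index:
                ax.set_axis_off()
                continue
            row = plate.plate_meta.loc[well]
            if row.get("success") is False:
                ax.set_facecolor("#fde8e8")
            _scatter(ax, data[data["well"] == well], spec)
            ax.set_xlim(*xlim)
            ax.set_ylim(*ylim)
            if i == 0:
                ax.set_title(str(c), fontsize=8)
            if j == 0:
                ax.set_ylabel(r, rotation=0, fontsize=8, labelpad=10)
    fig.suptitle(plate.name)
    fig.savefig(path)
    plt.close(fig)
    return path
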