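"""Radar-chart rendering of polygonal language profiles.

The chart is a Cartesian plane with the four operant axes on the
half-axes (echoic +x, mand +y, sequelic -x, tact -y under the canonical
order), the profile polygon(s), an optional centroid marker "c", the
optional property-space circle of radius C, and a companion line graph of
the first moment of area over age.

SVG output is deterministic for fixed input: a fixed hash salt and no
embedded creation date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
from matplotlib.patches import Circle, Polygon

from . import plp_geometry
from .analysis import SeriesRecord
from .plp_geometry import RadarConfig, build_profile
from .vox_data import AxisValues

logger = logging.getLogger(__name__)

_SVG_HASHSALT = "voxplp"

# one fill/edge color per overlay slot; cycles beyond five
_PALETTE = ("#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3", "#937860")


@dataclass(frozen=True)
class PlotSpec:
    """What to draw on one radar chart.

    More than four or five overlaid series are hard to read on a radar
    chart, so exceeding ``max_overlays`` logs a warning (it does not fail).
    The centroid is marked only when a single profile is shown — overlapped
    displays prohibit centroid plotting.
    """

    profiles: tuple[tuple[str, AxisValues], ...]
    show_centroid: bool = True
    show_property_circle: bool = True
    max_overlays: int = 5
    output_format: str = "svg"

    def __post_init__(self) -> None:
        if self.max_overlays < 1:
            raise ValueError("max_overlays must be >= 1")
        if self.output_format not in ("svg", "png"):
            raise ValueError(f"output format must be 'svg' or 'png', got {self.output_format!r}")


def render_radar(spec: PlotSpec, config: RadarConfig) -> plt.Figure:
    """Draw one radar chart; returns the matplotlib figure.

    Axes sit at 90 degrees (four operants), share one linear scale with
    maximum C when the property radius is configured (so the property
    circle circumscribes the plot), and are labeled with the operant names.
    """
    if not spec.profiles:
        raise ValueError("nothing to plot: PlotSpec has zero profiles")
    if len(spec.profiles) > spec.max_overlays:
        logger.warning(
            "plotting %d profiles exceeds the overlay limit of %d; "
            "radar charts become hard to read beyond four or five series",
            len(spec.profiles),
            spec.max_overlays,
        )

    plps = [build_profile(values, config) for _, values in spec.profiles]
    vmax = max((max(p.axis_values.as_tuple()) for p in plps), default=0.0)
    limit = config.property_radius if config.property_radius is not None else max(vmax, 1.0)

    fig, ax = plt.subplots(figsize=(5.2, 5.2))
    pad = 1.18 * limit
    ax.set_xlim(-pad, pad)
    ax.set_ylim(-pad, pad)
    ax.set_aspect("equal")
    ax.axis("off")

    units = plp_geometry.axis_unit_vectors(config.n_axes)
    for label, (ux, uy) in zip(config.axis_order, units):
        ax.plot([0, limit * ux], [0, limit * uy], color="0.55", lw=0.9, zorder=1)
        ax.annotate(
            label.capitalize(),
            (1.10 * limit * ux, 1.10 * limit * uy),
            ha="center",
            va="center",
            fontsize=10,
        )

    if spec.show_property_circle and config.property_radius is not None:
        ax.add_patch(
            Circle((0, 0), config.property_radius, fill=False, ls=":", color="0.4", lw=1.0)
        )

    for i, ((label, _), plp) in enumerate(zip(spec.profiles, plps)):
        color = _PALETTE[i % len(_PALETTE)]
        if plp_geometry.polygon_area(plp) > 0:
            ax.add_patch(
                Polygon(
                    list(plp.vertices),
                    closed=True,
                    facecolor=color,
                    edgecolor=color,
                    alpha=0.35,
                    lw=1.6,
                    label=label,
                    zorder=2,
                )
            )
            ax.plot(*zip(*(list(plp.vertices) + [plp.vertices[0]])), color=color, lw=1.6)
        else:  # degenerate profile: a point at the origin
            ax.plot([0], [0], marker="o", ms=4, color=color, label=label)

    if spec.show_centroid and len(plps) == 1:
        center = plp_geometry.centroid(plps[0])
        if center is not None:
            ax.annotate(
                "c", center, ha="center", va="center", fontsize=11, fontweight="bold"
            )
    if len(spec.profiles) > 1:
        ax.legend(loc="upper right", fontsize=8, frameon=False)
    return fig


def render_q_timeseries(
    series: SeriesRecord,
    baseline_end: str | None = None,
) -> plt.Figure:
    """Line graph of the first moment of area over age.

    Ages (YY:MM) go on the abscissa, Q on the ordinate.  If
    ``baseline_end`` names a timepoint age, the segment up to and including
    it is drawn dashed — the convention for a presumed (baseline) language
    trajectory preceding direct observation.
    """
    ages = [t.age for t in series.timepoints]
    qs = [t.descriptors.first_moment for t in series.timepoints]
    if any(q is None for q in qs):
        raise ValueError("first moment undefined; configure the property radius C")

    fig, ax = plt.subplots(figsize=(5.6, 3.4))
    xs = list(range(len(ages)))
    if baseline_end is not None and baseline_end in ages:
        cut = ages.index(baseline_end)
        ax.plot(xs[: cut + 1], qs[: cut + 1], "o--", color="#4c72b0")
        ax.plot(xs[cut:], qs[cut:], "o-", color="#4c72b0")
    else:
        ax.plot(xs, qs, "o-", color="#4c72b0")
    ax.set_xticks(xs, ages)
    ax.set_xlabel("Age (YY:MM)")
    ax.set_ylabel("First moment of area (Q)")
    ax.spines[["top", "right"]].set_visible(False)
    fig.tight_layout()
    return fig


def save_figure(fig: plt.Figure, path: str | Path, fmt: str | None = None) -> Path:
    """Write a figure to SVG or PNG; SVG bytes are reproducible.

    Determinism is achieved by pinning the SVG hash salt (element ids) and
    stripping the creation date from the metadata.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "svg"
    if fmt == "svg":
        # fonttype "none" keeps labels as real <text> elements (searchable,
        # structurally testable) instead of outlined glyph paths
        with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT, "svg.fonttype": "none"}):
            fig.savefig(path, format="svg", metadata={"Date": None})
    elif fmt == "png":
        fig.savefig(path, format="png", dpi=150)
    else:
        raise ValueError(f"unknown figure format {fmt!r}")
    return path
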