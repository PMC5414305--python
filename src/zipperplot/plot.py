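"""Zipper visualization: rank hits by distance and draw the zipper.

Features are ranked by |distance| (rank 1 = closest, drawn at the top), each
drawn as a horizontal peak segment anchored at its near edge relative to a
central vertical TSS axis.  Peaks overlapping the TSS sit on the axis, so a
fully supported feature set closes the zipper at the top; segments open
sideways as peaks lie further away.  Only the part of each peak inside the
+/- window is drawn; peaks entirely outside keep their rank but show nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .query import PeakHit
from .stats import WINDOW_DEFAULT, ZipperStats

__all__ = ["ZipperRow", "ZipperGeometry", "rank_hits", "build_geometry", "render"]


@dataclass(frozen=True)
class ZipperRow:
    rank: int  # 1-based, 1 = smallest |distance|
    distance: int | None
    extent: tuple[float, float] | None  # drawn [x0, x1] relative to the TSS, or None
    enrichment: float | None


@dataclass(frozen=True)
class ZipperGeometry:
    rows: tuple[ZipperRow, ...]
    window_halfwidth: int = WINDOW_DEFAULT


def rank_hits(hits: Sequence[PeakHit]) -> list[PeakHit]:
    """Stable sort by |distance| ascending; ties by signed distance
    descending (overlaps/downstream first), then input order; missing hits
    last in input order."""

    def key(item: tuple[int, PeakHit]):
        i, h = item
        if h.distance is None:
            return (1, float("inf"), 0, i)
        return (0, abs(h.distance), -h.distance, i)

    return [h for _, h in sorted(enumerate(hits), key=key)]


def build_geometry(ranked: Sequence[PeakHit], w: int = WINDOW_DEFAULT) -> ZipperGeometry:
    """Compute drawable extents for already-ranked hits.

    Each peak is drawn from its near edge (at the signed distance) extending
    by its width away from the TSS, truncated at the +/- window bounds; rows
    whose peak lies entirely outside the window (or is missing) keep their
    rank with no drawable extent.
    """
    if w <= 0:
        raise ValueError("window half-width must be positive")
    rows: list[ZipperRow] = []
    for rank, h in enumerate(ranked, start=1):
        if h.distance is None:
            rows.append(ZipperRow(rank, None, None, None))
            continue
        d, width = h.distance, h.peak_width
        if abs(d) > w:
            rows.append(ZipperRow(rank, d, None, h.enrichment))
            continue
        if d >= 0:  # near edge downstream (or overlap, drawn downstream)
            x0, x1 = float(d), float(min(d + width, w))
        else:
            x0, x1 = float(max(d - width, -w)), float(d)
        rows.append(ZipperRow(rank, d, (x0, x1), h.enrichment))
    return ZipperGeometry(tuple(rows), w)


def render(
    geom: ZipperGeometry,
    stats: ZipperStats | None,
    path: str | Path,
    fmt: str | None = None,
) -> Path:
    """Render the zipper plot to SVG or PNG.

    Rank runs down the y-axis (rank 1 at the top); enrichment (tpm or
    signalValue) maps to colour on a log1p scale.  Output is deterministic:
    identical geometry and stats give byte-identical SVG.
    """
    import matplotlib

    matplotlib.rcParams["svg.hashsalt"] = "zipperplot"
    import matplotlib.pyplot as plt
    from matplotlib import colormaps
    from matplotlib.colors import Normalize
    from matplotlib.lines import Line2D

    if not geom.rows:
        raise ValueError("cannot render an empty geometry")
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "svg")
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported format {fmt!r}")

    n = len(geom.rows)
    w = geom.window_halfwidth
    enr = [r.enrichment for r in geom.rows if r.enrichment is not None]
    vmax = max(np.log1p(enr).max(), 1.0) if enr else 1.0
    norm = Normalize(vmin=0.0, vmax=float(vmax))
    cmap = colormaps["viridis"]

    fig_h = min(10.0, max(2.5, 0.9 + 0.035 * n))
    fig, ax = plt.subplots(figsize=(7.0, fig_h))
    for row in geom.rows:
        if row.extent is None:
            continue
        colour = cmap(norm(float(np.log1p(row.enrichment or 0.0))))
        line = Line2D(
            row.extent, (row.rank, row.rank), color=colour, linewidth=1.2, solid_capstyle="butt"
        )
        line.set_gid(f"zipper-peak-{row.rank}")
        ax.add_line(line)
    ax.axvline(0.0, color="black", linewidth=0.8, zorder=3)
    ax.set_xlim(-w, w)
    ax.set_ylim(n + 1, 0)  # rank 1 at the top
    ax.set_xlabel("distance to TSS (nt)")
    ax.set_ylabel("feature rank")
    ax.set_title("Zipper plot")
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, label="log1p(enrichment)")

    if stats is not None:
        txt = (
            f"ZH = {stats.zh:.4g}\n"
            f"AUZ_global = {stats.auz_global:.4g}\n"
            f"AUZ_window = {stats.auz_window:.4g}"
        )
        if stats.auz_pval is not None:
            txt += f"\nAUZ_pval = {stats.auz_pval:.4g} ({stats.reps} reps)"
        ax.text(
            0.02,
            0.02,
            txt,
            transform=ax.transAxes,
            fontsize=8,
            va="bottom",
            ha="left",
            family="monospace",
            bbox={"boxstyle": "round", "facecolor": "white", "alpha": 0.8},
        )

    metadata = {"Date": None} if fmt == "svg" else None
    fig.savefig(path, format=fmt, dpi=150, metadata=metadata)
    plt.close(fig)
    return path
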