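"""Sequence Bundles rendering: thread layout, SVG emission, PNG rasterization.

A bundle is a grid with the alphabet on the y-axis (in a chosen biochemical
ordering, with an optional gap row below a gutter) and alignment positions on
the x-axis. Each sequence is one semi-opaque thread: a chain of cubic Bezier
segments through one anchor per column, placed in the grid cell of its symbol.
Sequences sharing a cell are stacked into evenly spaced lanes inside a
vertical band of the cell so that individual threads remain distinguishable.

Rendering is a pure function: identical inputs yield byte-identical SVG text
and PNG bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.sax.saxutils import escape, quoteattr

import numpy as np

from .alignment import MSA, GroupAssignment, Selection
from .errors import CapabilityError, InputError

MARGIN_LEFT = 48
MARGIN_RIGHT = 16
MARGIN_TOP = 24
MARGIN_BOTTOM = 32
GAP_GUTTER = 8


def auto_thread_opacity(n_seq: int) -> float:
    """Default opacity scales down with bundle size so dense bundles stay legible."""
    return min(1.0, max(0.02, 8.0 / n_seq))


@dataclass(frozen=True)
class RenderSpec:
    """Knobs of the bundle rendering engine (dimensions in CSS px)."""

    cell_width: float = 24.0
    cell_height: float = 24.0
    curvature: float = 0.35          # horizontal Bezier handle, fraction of cell_width
    thread_opacity: float | None = None  # None = auto from n_seq
    thread_width: float = 1.0
    ordering_name: str | None = None     # None = alphabet native order
    default_color: str = "#404040"
    selection_color: str = "#d62728"
    stack_band: float = 0.6          # fraction of cell height usable for lanes
    max_lanes: int = 32
    marker_band_height: float = 10.0
    marker_color: str = "#2ca02c"
    show_gap_row: bool = True

    def __post_init__(self):
        if not 0 <= self.curvature <= 0.5:
            raise InputError(f"curvature must be in [0, 0.5], got {self.curvature}")
        if not 0 <= self.stack_band <= 1:
            raise InputError(f"stack_band must be in [0, 1], got {self.stack_band}")
        for name in ("cell_width", "cell_height", "thread_width",
                     "marker_band_height"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.thread_opacity is not None and not 0 < self.thread_opacity <= 1:
            raise InputError("thread_opacity must be in (0, 1]")
        if self.max_lanes < 1:
            raise InputError("max_lanes must be >= 1")


@dataclass
class BundleLayout:
    """Computed geometry of a bundle: one anchor per (sequence, column)."""

    anchors: np.ndarray          # (n_seq, n_col, 2); NaN where a gap is skipped
    symbol_rows: list[str]       # top-to-bottom y-axis order (no gap)
    row_y: dict[str, float]      # symbol (incl. gap if shown) -> cell center y
    col_x: np.ndarray            # (n_col,) column center x
    width: float
    height: float
    grid_top: float
    grid_bottom: float
    spec: RenderSpec
    labels: list[str]
    thread_opacity: float


def layout_threads(msa: MSA, spec: RenderSpec | None = None) -> BundleLayout:
    """Deterministic thread layout.

    The stacking lane of a sequence within a cell is its rank (by row index)
    among the sequences sharing that cell, modulo ``max_lanes``; lanes are
    evenly spaced within the central band of the cell. Gap symbols are routed
    to the dedicated gap row, or skipped (NaN anchor, segment interpolated)
    when ``show_gap_row`` is off.
    """
    spec = spec or RenderSpec()
    gap = msa.alphabet.gap_symbol
    symbol_rows = list(msa.alphabet.ordering(spec.ordering_name))

    row_y: dict[str, float] = {}
    for r, sym in enumerate(symbol_rows):
        row_y[sym] = MARGIN_TOP + spec.marker_band_height + (r + 0.5) * spec.cell_height
    grid_top = MARGIN_TOP + spec.marker_band_height
    grid_bottom = grid_top + len(symbol_rows) * spec.cell_height
    height = grid_bottom
    if spec.show_gap_row:
        row_y[gap] = grid_bottom + GAP_GUTTER + 0.5 * spec.cell_height
        height = grid_bottom + GAP_GUTTER + spec.cell_height
    height += MARGIN_BOTTOM

    col_x = MARGIN_LEFT + (np.arange(msa.n_col) + 0.5) * spec.cell_width
    width = MARGIN_LEFT + msa.n_col * spec.cell_width + MARGIN_RIGHT

    # cell occupancy: (col, symbol) -> sequences routed there, in row order
    anchors = np.full((msa.n_seq, msa.n_col, 2), np.nan)
    band = spec.stack_band * spec.cell_height
    for j in range(msa.n_col):
        cells: dict[str, list[int]] = {}
        for i, row in enumerate(msa.rows):
            ch = row[j]
            if ch == gap and not spec.show_gap_row:
                continue
            cells.setdefault(ch, []).append(i)
        for sym, members in cells.items():
            n_lanes = min(len(members), spec.max_lanes)
            for rank, i in enumerate(members):
                lane = rank % spec.max_lanes
                if n_lanes > 1:
                    offset = band * ((lane + 0.5) / n_lanes - 0.5)
                else:
                    offset = 0.0
                anchors[i, j, 0] = col_x[j]
                anchors[i, j, 1] = row_y[sym] + offset

    opacity = (
        spec.thread_opacity
        if spec.thread_opacity is not None
        else auto_thread_opacity(msa.n_seq)
    )
    return BundleLayout(
        anchors=anchors,
        symbol_rows=symbol_rows,
        row_y=row_y,
        col_x=col_x,
        width=width,
        height=height,
        grid_top=grid_top,
        grid_bottom=grid_bottom,
        spec=spec,
        labels=list(msa.labels),
        thread_opacity=opacity,
    )


def _f(v: float) -> str:
    """Stable short float formatting for SVG attributes."""
    return f"{v:.3f}".rstrip("0").rstrip(".")


def thread_path_d(points: np.ndarray, curvature: float, cell_width: float) -> str:
    """SVG path data for one thread through its non-NaN anchors.

    Each inter-anchor segment is a cubic Bezier whose control points sit at
    horizontal offsets +-curvature*cell_width from the endpoints (curvature 0
    degenerates to straight segments with collinear control points).
    """
    pts = points[~np.isnan(points[:, 0])]
    if len(pts) == 0:
        return ""
    dx = curvature * cell_width
    parts = [f"M {_f(pts[0, 0])},{_f(pts[0, 1])}"]
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        parts.append(
            f"C {_f(x1 + dx)},{_f(y1)} {_f(x2 - dx)},{_f(y2)} {_f(x2)},{_f(y2)}"
        )
    return " ".join(parts)


def _thread_color(
    idx0: int, spec: RenderSpec, groups: GroupAssignment | None,
    selected0: frozenset[int],
) -> str:
    """Colour of the thread at 0-based row ``idx0`` (membership is 1-based)."""
    if idx0 in selected0:
        return spec.selection_color
    if groups is not None:
        g = groups.group_of(idx0 + 1)
        if g is not None:
            return groups.colors.get(g, spec.default_color)
    return spec.default_color


def render_svg(
    layout: BundleLayout,
    spec: RenderSpec | None = None,
    groups: GroupAssignment | None = None,
    selection: Selection | None = None,
    markers: list[float] | np.ndarray | None = None,
) -> str:
    """Emit the bundle as an SVG 1.1 document (deterministic text).

    Threads are ``<path class="thread" data-label="...">`` elements; optional
    site markers are ``<rect class="site-marker">`` rectangles above the grid
    whose fill-opacity is the provided per-column value.
    """
    spec = spec or layout.spec
    n_seq, n_col = layout.anchors.shape[:2]
    if markers is not None and len(markers) != n_col:
        raise InputError(
            f"markers has {len(markers)} values but the alignment has {n_col} columns"
        )
    selected = selection.seq_indices if selection is not None else frozenset()
    selected0 = frozenset(i - 1 for i in selected)

    out = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(layout.width)}" height="{_f(layout.height)}" '
        f'viewBox="0 0 {_f(layout.width)} {_f(layout.height)}">'
    )
    out.append('<rect class="background" width="100%" height="100%" fill="#ffffff"/>')

    # grid
    out.append('<g class="grid" stroke="#dddddd" stroke-width="0.5">')
    rows = len(layout.symbol_rows)
    for r in range(rows + 1):
        y = layout.grid_top + r * spec.cell_height
        out.append(
            f'<line x1="{_f(MARGIN_LEFT)}" y1="{_f(y)}" '
            f'x2="{_f(MARGIN_LEFT + n_col * spec.cell_width)}" y2="{_f(y)}"/>'
        )
    for c in range(n_col + 1):
        x = MARGIN_LEFT + c * spec.cell_width
        out.append(
            f'<line x1="{_f(x)}" y1="{_f(layout.grid_top)}" '
            f'x2="{_f(x)}" y2="{_f(layout.grid_bottom)}"/>'
        )
    out.append("</g>")

    # axis labels
    out.append('<g class="axis" font-family="monospace" font-size="10" fill="#000000">')
    for sym in layout.symbol_rows:
        y = layout.row_y[sym]
        out.append(
            f'<text x="{_f(MARGIN_LEFT - 10)}" y="{_f(y + 3)}" '
            f'text-anchor="middle">{escape(sym)}</text>'
        )
    if spec.show_gap_row:
        gap_syms = [s for s in layout.row_y if s not in layout.symbol_rows]
        for sym in gap_syms:
            out.append(
                f'<text x="{_f(MARGIN_LEFT - 10)}" y="{_f(layout.row_y[sym] + 3)}" '
                f'text-anchor="middle">{escape(sym)}</text>'
            )
    label_y = layout.height - MARGIN_BOTTOM + 14
    for c in range(n_col):
        out.append(
            f'<text x="{_f(float(layout.col_x[c]))}" y="{_f(label_y)}" '
            f'text-anchor="middle">{c + 1}</text>'
        )
    out.append("</g>")

    # site markers
    if markers is not None:
        out.append(f'<g class="site-markers" fill="{spec.marker_color}">')
        for c in range(n_col):
            x = MARGIN_LEFT + c * spec.cell_width
            out.append(
                f'<rect class="site-marker" x="{_f(x)}" '
                f'y="{_f(layout.grid_top - spec.marker_band_height)}" '
                f'width="{_f(spec.cell_width)}" '
                f'height="{_f(spec.marker_band_height)}" '
                f'fill-opacity="{_f(float(markers[c]))}"/>'
            )
        out.append("</g>")

    # threads
    out.append('<g class="threads" fill="none">')
    for i in range(n_seq):
        d = thread_path_d(layout.anchors[i], spec.curvature, spec.cell_width)
        if not d:
            continue
        color = _thread_color(i, spec, groups, selected0)
        out.append(
            f'<path class="thread" data-label={quoteattr(layout.labels[i])} '
            f'd="{d}" stroke="{color}" '
            f'stroke-width="{_f(spec.thread_width)}" '
            f'stroke-opacity="{_f(layout.thread_opacity)}"/>'
        )
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _sample_bezier(p0, p1, p2, p3, n: int = 24) -> list[tuple[float, float]]:
    t = np.linspace(0.0, 1.0, n)
    mt = 1 - t
    x = mt**3 * p0[0] + 3 * mt**2 * t * p1[0] + 3 * mt * t**2 * p2[0] + t**3 * p3[0]
    y = mt**3 * p0[1] + 3 * mt**2 * t * p1[1] + 3 * mt * t**2 * p2[1] + t**3 * p3[1]
    return list(zip(x.tolist(), y.tolist()))


def render_png(
    layout: BundleLayout,
    spec: RenderSpec | None = None,
    groups: GroupAssignment | None = None,
    selection: Selection | None = None,
    markers: list[float] | np.ndarray | None = None,
    dpi: int = 300,
) -> bytes:
    """Rasterize the identical bundle geometry to PNG bytes.

    The image is scaled by dpi/96 (CSS px are 96 per inch), so doubling the
    dpi doubles both pixel dimensions. Deterministic: identical inputs yield
    byte-identical PNGs.
    """
    try:
        from PIL import Image, ImageDraw
    except ImportError as exc:  # pragma: no cover
        raise CapabilityError("PNG rasterization requires Pillow") from exc

    spec = spec or layout.spec
    n_seq, n_col = layout.anchors.shape[:2]
    if markers is not None and len(markers) != n_col:
        raise InputError(
            f"markers has {len(markers)} values but the alignment has {n_col} columns"
        )
    selected = selection.seq_indices if selection is not None else frozenset()
    selected0 = frozenset(i - 1 for i in selected)

    scale = dpi / 96.0
    W = int(round(layout.width * scale))
    H = int(round(layout.height * scale))
    img = Image.new("RGB", (W, H), "#ffffff")
    draw = ImageDraw.Draw(img)

    def s(v: float) -> float:
        return v * scale

    # grid
    grid_color = (221, 221, 221)
    for r in range(len(layout.symbol_rows) + 1):
        y = s(layout.grid_top + r * spec.cell_height)
        draw.line(
            [(s(MARGIN_LEFT), y), (s(MARGIN_LEFT + n_col * spec.cell_width), y)],
            fill=grid_color, width=max(1, int(round(0.5 * scale))),
        )
    for c in range(n_col + 1):
        x = s(MARGIN_LEFT + c * spec.cell_width)
        draw.line(
            [(x, s(layout.grid_top)), (x, s(layout.grid_bottom))],
            fill=grid_color, width=max(1, int(round(0.5 * scale))),
        )

    # markers
    if markers is not None:
        base = _hex_to_rgb(spec.marker_color)
        for c in range(n_col):
            x = s(MARGIN_LEFT + c * spec.cell_width)
            y0 = s(layout.grid_top - spec.marker_band_height)
            overlay = Image.new("RGBA", (W, H), (0, 0, 0, 0))
            odraw = ImageDraw.Draw(overlay)
            alpha = int(round(255 * float(markers[c])))
            odraw.rectangle(
                [x, y0, x + s(spec.cell_width), s(layout.grid_top)],
                fill=base + (alpha,),
            )
            img = Image.alpha_composite(img.convert("RGBA"), overlay).convert("RGB")
        draw = ImageDraw.Draw(img)

    # threads: per-thread RGBA overlay so semi-opaque strokes accumulate
    lw = max(1, int(round(spec.thread_width * scale)))
    alpha = int(round(255 * layout.thread_opacity))
    img = img.convert("RGBA")
    for i in range(n_seq):
        pts = layout.anchors[i][~np.isnan(layout.anchors[i][:, 0])]
        if len(pts) == 0:
            continue
        color = _hex_to_rgb(_thread_color(i, spec, groups, selected0)) + (alpha,)
        poly: list[tuple[float, float]] = [(s(pts[0][0]), s(pts[0][1]))]
        dx = spec.curvature * spec.cell_width
        for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
            poly.extend(
                (s(px), s(py))
                for px, py in _sample_bezier(
                    (x1, y1), (x1 + dx, y1), (x2 - dx, y2), (x2, y2)
                )[1:]
            )
        overlay = Image.new("RGBA", (W, H), (0, 0, 0, 0))
        ImageDraw.Draw(overlay).line(poly, fill=color, width=lw, joint="curve")
        img = Image.alpha_composite(img, overlay)
    img = img.convert("RGB")

    import io

    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    if len(color) != 6:
        raise InputError(f"expected #rrggbb colour, got {color!r}")
    return tuple(int(color[i:i + 2], 16) for i in (0, 2, 4))


def render_msa_svg(
    msa: MSA,
    spec: RenderSpec | None = None,
    groups: GroupAssignment | None = None,
    selection: Selection | None = None,
    markers=None,
) -> str:
    """Convenience: layout + SVG in one call."""
    spec = spec or RenderSpec()
    return render_svg(layout_threads(msa, spec), spec, groups, selection, markers)
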