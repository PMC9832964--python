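"""Figure generation: deterministic SVG, plus PNG/JPG/PDF export.

The SVG document is the source of truth and is a pure function of
(model, layout, style): element order is fixed (background, ribbons sorted
by absolute coefficient ascending so the strongest correlations draw on
top, rim arcs, domain labels) and every numeric attribute is written with a
fixed 4-decimal format, so two renders of identical input are byte-identical
and can be pinned by snapshot tests.

Each ribbon and rim arc embeds an SVG ``<title>`` element — the static
counterpart of an interactive hover tooltip, also what screen readers and
browsers surface on focus. A ribbon's tooltip reads
``var1 (dom1) ↔ var2 (dom2): coef``.

Raster (PNG/JPG) and PDF exports re-draw the identical scene geometry with
matplotlib's Agg backend at the declared pixel size; SVG export itself needs
nothing beyond the standard library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
from xml.sax.saxutils import escape

from .errors import ConversionFailure, InconsistentInput, UnsupportedFormat
from .layout import GlobeLayout, unit_point
from .model import GlobeModel, Ribbon
from .settings import StyleSettings

EXPORT_FORMATS = ("svg", "png", "jpg", "pdf")

_RIM_COLOR = "#888888"
_RIBBON_OPACITY = 0.75
_ELLIPSIS = "…"


def _fmt(v: float) -> str:
    # Fixed 4-decimal formatting keeps the SVG byte-stable; -0.0 is folded
    # into 0.0 so the sign of a rounding error cannot leak into the bytes.
    s = f"{v:.4f}"
    return "0.0000" if s == "-0.0000" else s


@dataclass(frozen=True)
class FigureDocument:
    """A rendered figure: complete SVG text plus its declared pixel size."""

    svg_text: str
    width_px: int
    height_px: int
    _scene: Optional[tuple] = field(default=None, repr=False, compare=False)


def truncate_label(label: str, max_chars: int) -> str:
    """Cut a label to ``max_chars`` with a trailing ellipsis when cut."""
    if len(label) <= max_chars:
        return label
    return label[: max_chars - 1] + _ELLIPSIS


def _text_color(background_hex: str) -> str:
    r, g, b = (int(background_hex.lstrip("#")[i:i + 2], 16) for i in (0, 2, 4))
    luminance = 0.2126 * r + 0.7152 * g + 0.0722 * b
    return "#1a1a1a" if luminance > 127.5 else "#f2f2f2"


def ribbon_width(coef: float, style: StyleSettings) -> float:
    """Stroke width in px: linear in |coef| between the configured bounds."""
    return style.ribbon_min_width + (style.ribbon_max_width - style.ribbon_min_width) * abs(coef)


def ribbon_tooltip(ribbon: Ribbon) -> str:
    return (f"{ribbon.variable1} ({ribbon.domain1}) ↔ "
            f"{ribbon.variable2} ({ribbon.domain2}): {ribbon.coef:g}")


def _check_consistency(model: GlobeModel, layout: GlobeLayout) -> None:
    if set(model.domain_names) != set(layout.domain_spans):
        raise InconsistentInput("model and layout disagree on the domain set")
    if len(layout.ribbon_geoms) != len(model.ribbons):
        raise InconsistentInput(
            f"layout has {len(layout.ribbon_geoms)} ribbon paths for "
            f"{len(model.ribbons)} model ribbons"
        )
    for rb in model.ribbons:
        for dom, var in ((rb.domain1, rb.variable1), (rb.domain2, rb.variable2)):
            if (dom, var) not in layout.variable_anchors:
                raise InconsistentInput(f"no anchor for variable {var!r} in {dom!r}")


class _Scene:
    """Pixel-space geometry shared by the SVG writer and matplotlib export.

    SVG conventions: origin top-left, y down, rotations clockwise.
    """

    def __init__(self, model: GlobeModel, layout: GlobeLayout, style: StyleSettings):
        self.model, self.layout, self.style = model, layout, style
        self.size = style.figure_size_px
        self.cx = self.cy = self.size / 2.0
        self.radius = 0.36 * self.size          # ribbon endpoint radius
        self.rim_radius = self.radius * 1.035   # rim arc centerline
        self.rim_width = max(2.0, self.radius * 0.045)
        self.label_radius = self.radius * 1.10

    def to_px(self, pt: tuple[float, float], r: float | None = None) -> tuple[float, float]:
        r = self.radius if r is None else r
        return (self.cx + pt[0] * r, self.cy - pt[1] * r)

    def draw_order(self) -> list[int]:
        """Ribbon indices sorted by |coef| ascending, ties by input order."""
        return sorted(range(len(self.model.ribbons)),
                      key=lambda i: (abs(self.model.ribbons[i].coef), i))

    def ribbon_px(self, i: int) -> tuple[tuple[float, float], ...]:
        geom = self.layout.ribbon_geoms[i]
        return tuple(self.to_px(p) for p in geom.control_points())

    def arcs(self) -> list[tuple[str, float, float, str]]:
        """(domain name, start_deg, end_deg, tooltip) per rim arc, in rim order."""
        out = []
        for name, span in self.layout.domain_spans.items():
            n = self.model.domain(name).size
            plural = "" if n == 1 else "s"
            out.append((name, span.start_deg, span.end_deg,
                        f"{name}: {n} variable{plural}"))
        return out

    def labels(self) -> list[tuple[float, float, float, str, str]]:
        """(x, y, rotation_deg, anchor, text) per domain label, in rim order."""
        out = []
        for name, span in self.layout.domain_spans.items():
            mid = span.mid_deg
            x, y = self.to_px(unit_point(mid), self.label_radius)
            rot = mid - 90.0
            anchor = "start"
            if 180.0 < mid < 360.0:  # flip left-half labels to read outward
                rot += 180.0
                anchor = "end"
            out.append((x, y, rot, anchor,
                        truncate_label(name, self.style.label_max_chars)))
        return out


def render_svg(model: GlobeModel, layout: GlobeLayout,
               style: StyleSettings | None = None) -> FigureDocument:
    """Render a globe as a complete, deterministic SVG document.

    Ribbons with positive coefficients use ``style.positive_color`` (class
    ``pos``), negative ``style.negative_color`` (class ``neg``); each carries
    a ``<title>`` tooltip. One rim arc and one (possibly truncated) label per
    domain.
    """
    style = style or StyleSettings()
    _check_consistency(model, layout)
    sc = _Scene(model, layout, style)
    size = sc.size

    lines: list[str] = []
    lines.append('<?xml version="1.0" encoding="UTF-8"?>')
    lines.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">'
    )
    lines.append(
        "<desc>Correlation globe: variables on the rim grouped into domains; "
        "ribbons are pairwise correlations colored by sign "
        f"(threshold |coef| &gt; {model.threshold:g}).</desc>"
    )
    lines.append(
        f'<rect class="background" x="0" y="0" width="{size}" height="{size}" '
        f'fill="{style.background_color}"/>'
    )

    lines.append('<g class="ribbons" fill="none" stroke-linecap="round" '
                 f'stroke-opacity="{_fmt(_RIBBON_OPACITY)}">')
    for i in sc.draw_order():
        rb = model.ribbons[i]
        (x0, y0), (x1, y1), (x2, y2), (x3, y3) = sc.ribbon_px(i)
        cls = "pos" if rb.coef > 0 else "neg"
        color = style.positive_color if rb.coef > 0 else style.negative_color
        d = (f"M {_fmt(x0)},{_fmt(y0)} C {_fmt(x1)},{_fmt(y1)} "
             f"{_fmt(x2)},{_fmt(y2)} {_fmt(x3)},{_fmt(y3)}")
        lines.append(
            f'<path class="ribbon {cls}" d="{d}" stroke="{color}" '
            f'stroke-width="{_fmt(ribbon_width(rb.coef, style))}">'
            f"<title>{escape(ribbon_tooltip(rb))}</title></path>"
        )
    lines.append("</g>")

    lines.append(f'<g class="rim" fill="none" stroke="{_RIM_COLOR}" '
                 f'stroke-width="{_fmt(sc.rim_width)}">')
    for name, start, end, tip in sc.arcs():
        x0, y0 = sc.to_px(unit_point(start), sc.rim_radius)
        x1, y1 = sc.to_px(unit_point(end), sc.rim_radius)
        large = 1 if (end - start) > 180.0 else 0
        d = (f"M {_fmt(x0)},{_fmt(y0)} A {_fmt(sc.rim_radius)},{_fmt(sc.rim_radius)} "
             f"0 {large},1 {_fmt(x1)},{_fmt(y1)}")
        lines.append(f'<path class="arc" d="{d}"><title>{escape(tip)}</title></path>')
    lines.append("</g>")

    text_fill = _text_color(style.background_color)
    lines.append(
        f'<g class="labels" font-family="Helvetica, Arial, sans-serif" '
        f'font-size="{_fmt(style.font_size)}pt" fill="{text_fill}">'
    )
    for x, y, rot, anchor, text in sc.labels():
        lines.append(
            f'<text class="domain-label" x="{_fmt(x)}" y="{_fmt(y)}" '
            f'text-anchor="{anchor}" dominant-baseline="middle" '
            f'transform="rotate({_fmt(rot)} {_fmt(x)} {_fmt(y)})">'
            f"{escape(text)}</text>"
        )
    lines.append("</g>")
    lines.append("</svg>")

    return FigureDocument(
        svg_text="\n".join(lines) + "\n",
        width_px=size, height_px=size,
        _scene=(model, layout, style),
    )


def export(figure: FigureDocument, format: str, path) -> None:
    """Write a figure to disk as svg, png, jpg or pdf.

    SVG is written verbatim (byte-identical to ``figure.svg_text``). The
    other formats re-draw the figure's scene at the declared pixel size and
    raise :class:`ConversionFailure` if the drawing backend is unavailable.
    """
    fmt = str(format).lower().lstrip(".")
    if fmt == "jpeg":
        fmt = "jpg"
    if fmt not in EXPORT_FORMATS:
        raise UnsupportedFormat(f"format must be one of {EXPORT_FORMATS}, got {format!r}")
    if fmt == "svg":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(figure.svg_text)
        return
    if figure._scene is None:
        raise ConversionFailure(
            "figure carries no scene geometry; re-render with render_svg()"
        )
    try:
        _export_matplotlib(figure, fmt, path)
    except (UnsupportedFormat, ConversionFailure):
        raise
    except Exception as exc:  # pragma: no cover - backend-dependent
        raise ConversionFailure(f"{fmt} conversion failed: {exc}") from exc


def export_html(figure: FigureDocument, path) -> None:
    """Self-contained HTML page with the SVG inline (native browser tooltips)."""
    body = figure.svg_text.split("\n", 1)[1]  # drop the XML declaration
    html = (
        "<!DOCTYPE html>\n<html lang=\"en\">\n<head>\n<meta charset=\"utf-8\">\n"
        "<title>Correlation globe</title>\n</head>\n<body>\n"
        + body + "</body>\n</html>\n"
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(html)


def _export_matplotlib(figure: FigureDocument, fmt: str, path) -> None:
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure as MplFigure
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path as MplPath

    model, layout, style = figure._scene
    sc = _Scene(model, layout, style)
    dpi = 100.0
    size = sc.size
    fig = MplFigure(figsize=(size / dpi, size / dpi), dpi=dpi)
    FigureCanvasAgg(fig)
    fig.patch.set_facecolor(style.background_color)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, size)
    ax.set_ylim(size, 0)  # y down, matching the SVG coordinate system
    ax.set_axis_off()
    ax.set_facecolor(style.background_color)

    px_to_pt = 72.0 / dpi

    for i in sc.draw_order():
        rb = model.ribbons[i]
        pts = sc.ribbon_px(i)
        mpath = MplPath(pts, [MplPath.MOVETO, MplPath.CURVE4,
                              MplPath.CURVE4, MplPath.CURVE4])
        color = style.positive_color if rb.coef > 0 else style.negative_color
        ax.add_patch(PathPatch(
            mpath, fill=False, edgecolor=color, alpha=_RIBBON_OPACITY,
            linewidth=ribbon_width(rb.coef, style) * px_to_pt,
            capstyle="round",
        ))

    for _name, start, end, _tip in sc.arcs():
        n_pts = max(16, int(end - start))
        xs, ys = [], []
        for j in range(n_pts + 1):
            ang = start + (end - start) * j / n_pts
            x, y = sc.to_px(unit_point(ang), sc.rim_radius)
            xs.append(x)
            ys.append(y)
        ax.plot(xs, ys, color=_RIM_COLOR, linewidth=sc.rim_width * px_to_pt,
                solid_capstyle="butt")

    text_color = _text_color(style.background_color)
    for x, y, rot, anchor, text in sc.labels():
        ax.text(
            x, y, text,
            rotation=-rot,  # matplotlib rotates counterclockwise on screen
            rotation_mode="anchor",
            ha="left" if anchor == "start" else "right",
            va="center", fontsize=style.font_size, color=text_color,
            family="sans-serif",
        )

    save_kwargs: dict = {"format": fmt, "dpi": dpi,
                         "facecolor": style.background_color}
    if fmt == "jpg":
        save_kwargs["pil_kwargs"] = {"quality": 92}
    fig.savefig(path, **save_kwargs)
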