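"""Rendering: canonical layout JSON export and SVG output.

The JSON export is the machine-readable surface of a layout: every
geometric contract (slot fixity, pip-count conservation, scale anchoring)
is expressible as a query over it, and the test suite treats it as the
oracle artifact.  Serialization is canonical — sorted keys, fixed 6-decimal
precision, no whitespace — so identical layouts produce byte-identical
documents and round-trips are fixed points.

The SVG renderer is deliberately backend-free: it emits plain SVG 1.1 with
one ``<g>`` per die (stable, label-derived ids) and one ``class="pip"``
circle per pip, each carrying a ``data-level`` attribute, so documents are
diffable and assertable with any XML parser.  Raster output, if needed, is
left to external converters.
"""

from __future__ import annotations

import json
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .dice_layout import DiceCell, PlotLayout
from .domino_layout import DominoCell
from .errors import DiceGlyphError
from .geo_layout import GeoLayout, project
from .legend import LegendSpec, build_legend  # re-exported

__all__ = [
    "RenderConfig",
    "SCHEMA_VERSION",
    "export_layout_json",
    "dumps_layout",
    "import_layout_json",
    "render_svg",
    "build_legend",
    "LegendSpec",
]

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class RenderConfig:
    """Pixel-level rendering options (all geometry else comes from the
    layout's own style)."""

    px_scale: float = 1.0
    font_family: str = "sans-serif"
    font_size: float = 10.0
    margin: float = 10.0
    map_width_px: float = 400.0
    show_legend: bool = True

    def __post_init__(self) -> None:
        if self.px_scale <= 0 or self.font_size <= 0 or self.margin < 0:
            raise DiceGlyphError("px_scale/font_size must be positive, margin nonnegative")


# ---------------------------------------------------------------------------
# JSON export


def _r6(x: float) -> float:
    return round(float(x), 6)


def _num(x):
    """NaN/inf are not valid JSON; export them as null."""
    x = float(x)
    return _r6(x) if math.isfinite(x) else None


def _levels_by_slot(layout: PlotLayout) -> dict[int, str]:
    return {slot: lev for lev, slot in layout.slot_map.assignment.items()}


def _export_cell(layout: PlotLayout, cell, grid: tuple[int, int]) -> dict:
    by_slot = _levels_by_slot(layout)
    coords = layout.slot_map.layout.coords
    base = {
        "row": cell.row_label,
        "col": cell.col_label,
        "grid": list(grid),
        "slots": [int(s) for s in cell.present_slots],
        "bg_group": cell.bg_group,
        "fill": cell.fill,
    }
    if isinstance(cell, DominoCell):
        halves = []
        for half in cell.halves:
            dots = []
            for d in half.dots:
                u, v = coords[d.slot]
                dots.append(
                    {
                        "slot": int(d.slot),
                        "level": by_slot[d.slot],
                        "u": _r6(u),
                        "v": _r6(v),
                        "color_value": _num(d.color_value),
                        "size_value": _num(d.size_value),
                        "tested": bool(d.tested),
                        "color": layout.scales.color(d.color_value)
                        if d.tested
                        else layout.scales.color.na_color,
                        "radius": _r6(
                            layout.scales.size(d.size_value)
                            if d.tested
                            else layout.scales.size.r_min
                        ),
                    }
                )
            halves.append({"split": half.split_level, "dots": dots})
        base["halves"] = halves
    else:
        pips = []
        for slot in cell.present_slots:
            u, v = coords[slot]
            pips.append(
                {
                    "slot": int(slot),
                    "level": by_slot[slot],
                    "u": _r6(u),
                    "v": _r6(v),
                    "color": layout.dot_colors[by_slot[slot]],
                    "radius": _r6(layout.style.dot_radius_frac),
                }
            )
        base["pips"] = pips
    return base


def _export_legend(legend: LegendSpec) -> dict:
    out: dict = {
        "dot_key": [
            {"level": lev, "slot": int(slot), "u": _r6(u), "v": _r6(v), "color": color}
            for lev, slot, (u, v), color in legend.dot_key
        ]
    }
    out["bg_key"] = [[g, c] for g, c in legend.bg_key] if legend.bg_key else None
    if legend.color_ramp:
        ramp = dict(legend.color_ramp)
        ramp["domain"] = list(ramp["domain"])
        ramp["stops"] = [[_r6(v), c] for v, c in ramp["stops"]]
        out["color_ramp"] = ramp
    else:
        out["color_ramp"] = None
    out["size_ladder"] = (
        [[_r6(v), _r6(r)] for v, r in legend.size_ladder] if legend.size_ladder else None
    )
    return out


def export_layout_json(layout: PlotLayout | GeoLayout) -> dict:
    """Canonical dict form of a layout (schema-versioned, 6-decimal floats)."""
    geo = None
    if isinstance(layout, GeoLayout):
        geo_layout = layout
        layout = layout.base
        w = RenderConfig().map_width_px
        lon0, lat0, lon1, lat1 = geo_layout.viewport
        h = w * (lat1 - lat0) / (lon1 - lon0)
        geo = {
            "projection": geo_layout.projection,
            "viewport": [_r6(v) for v in geo_layout.viewport],
            "map_px": [_r6(w), _r6(h)],
            "n_outlines": len(geo_layout.outlines),
            "placements": {
                loc: {
                    "lon": _r6(p.lon),
                    "lat": _r6(p.lat),
                    "glyph_scale": _r6(p.glyph_scale),
                    "x": _r6(project(p.lon, p.lat, geo_layout.viewport, w, h)[0]),
                    "y": _r6(project(p.lon, p.lat, geo_layout.viewport, w, h)[1]),
                }
                for loc, p in sorted(geo_layout.placements.items())
            },
        }

    style = layout.style
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "mode": layout.mode,
        "slot_map": {
            "variant": layout.slot_map.layout.variant,
            "levels": list(layout.slot_map.dot_levels),
            "coords": [[_r6(u), _r6(v)] for u, v in layout.slot_map.layout.coords],
        },
        "row_order": {"method": layout.row_order.method, "labels": list(layout.row_order.labels)},
        "col_order": {"method": layout.col_order.method, "labels": list(layout.col_order.labels)},
        "style": {
            "cell_px": _r6(style.cell_px),
            "dot_radius_frac": _r6(style.dot_radius_frac),
            "bg_alpha": _r6(style.bg_alpha),
            "split_orientation": style.split_orientation,
            "size_encoding": style.size_encoding,
            "neutral_fill": style.neutral_fill,
            "draw_empty": style.draw_empty,
        },
        "dot_colors": dict(sorted(layout.dot_colors.items())),
        "bg_colors": dict(sorted(layout.bg_colors.items())),
        "scales": None,
        "cells": [
            _export_cell(layout, cell, layout.grid_position(cell.row_label, cell.col_label))
            for cell in layout.cells
        ],
        "legend": _export_legend(layout.legend),
        "geo": geo,
    }
    if layout.scales is not None:
        doc["scales"] = {
            "color": {"vmax": _r6(layout.scales.color.vmax), "palette": layout.scales.color.palette},
            "size": {
                "vmax": _r6(layout.scales.size.vmax),
                "r_min": _r6(layout.scales.size.r_min),
                "r_max": _r6(layout.scales.size.r_max),
                "encoding": layout.scales.size.encoding,
            },
        }
    return doc


def dumps_layout(doc: dict) -> str:
    """Canonical JSON text: sorted keys, compact separators."""
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), allow_nan=False)


def import_layout_json(source: str | dict) -> dict:
    """Parse an exported layout document (inverse of :func:`dumps_layout`)."""
    doc = json.loads(source) if isinstance(source, str) else source
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise DiceGlyphError(
            f"unsupported layout schema {doc.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION!r}"
        )
    return doc


# ---------------------------------------------------------------------------
# SVG rendering


def _fmt(x: float) -> str:
    s = f"{float(x):.2f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


_ID_RE = re.compile(r"[^A-Za-z0-9_-]+")


def _sanitize(label: str) -> str:
    out = _ID_RE.sub("_", label).strip("_")
    return out or "x"


class _IdPool:
    def __init__(self) -> None:
        self.seen: set[str] = set()

    def get(self, base: str) -> str:
        candidate, k = base, 1
        while candidate in self.seen:
            k += 1
            candidate = f"{base}_{k}"
        self.seen.add(candidate)
        return candidate


def _die_group(
    parent: ET.Element,
    ids: _IdPool,
    layout: PlotLayout,
    cell,
    x0: float,
    y0: float,
    cell_px: float,
) -> None:
    style = layout.style
    g = ET.SubElement(
        parent,
        "g",
        {
            "id": ids.get(f"die-{_sanitize(cell.row_label)}-{_sanitize(cell.col_label)}"),
            "class": "die",
        },
    )
    is_domino = isinstance(cell, DominoCell)
    bg_attrs = {
        "x": _fmt(x0),
        "y": _fmt(y0),
        "width": _fmt(cell_px),
        "height": _fmt(cell_px),
        "fill": cell.fill,
        "stroke": "#555555",
        "stroke-width": "0.8",
    }
    if cell.bg_group is not None:
        bg_attrs["fill-opacity"] = _fmt(style.bg_alpha)
    ET.SubElement(g, "rect", bg_attrs)

    coords = layout.slot_map.layout.coords
    by_slot = _levels_by_slot(layout)

    if not is_domino:
        r = style.dot_radius_frac * cell_px
        for slot in cell.present_slots:
            u, v = coords[slot]
            level = by_slot[slot]
            ET.SubElement(
                g,
                "circle",
                {
                    "class": "pip",
                    "cx": _fmt(x0 + u * cell_px),
                    "cy": _fmt(y0 + (1.0 - v) * cell_px),
                    "r": _fmt(r),
                    "fill": layout.dot_colors[level],
                    "data-level": level,
                },
            )
        return

    vertical = style.split_orientation == "vertical"
    n_halves = len(cell.halves)
    for hi, half in enumerate(cell.halves):
        if vertical:
            hx, hy = x0 + hi * cell_px / n_halves, y0
            hw, hh = cell_px / n_halves, cell_px
        else:
            hx, hy = x0, y0 + hi * cell_px / n_halves
            hw, hh = cell_px, cell_px / n_halves
        if hi > 0:  # seam between halves
            ET.SubElement(
                g,
                "line",
                {
                    "x1": _fmt(hx),
                    "y1": _fmt(hy),
                    "x2": _fmt(hx + (0 if vertical else hw)),
                    "y2": _fmt(hy + (hh if vertical else 0)),
                    "stroke": "#555555",
                    "stroke-width": "0.8",
                },
            )
        for d in half.dots:
            u, v = coords[d.slot]
            level = by_slot[d.slot]
            if d.tested:
                color = layout.scales.color(d.color_value)
                r = layout.scales.size(d.size_value) * cell_px
                extra = {"fill": color}
            else:
                r = layout.scales.size.r_min * cell_px
                extra = {"fill": "none", "stroke": layout.scales.color.na_color, "stroke-width": "0.8"}
            ET.SubElement(
                g,
                "circle",
                {
                    "class": "pip",
                    "cx": _fmt(hx + u * hw),
                    "cy": _fmt(hy + (1.0 - v) * hh),
                    "r": _fmt(r),
                    "data-level": level,
                    "data-split": half.split_level,
                    **extra,
                },
            )


def _text(parent: ET.Element, x: float, y: float, content: str, cfg: RenderConfig, **attrs) -> None:
    el = ET.SubElement(
        parent,
        "text",
        {
            "x": _fmt(x),
            "y": _fmt(y),
            "font-family": cfg.font_family,
            "font-size": _fmt(cfg.font_size),
            "fill": "#222222",
            **attrs,
        },
    )
    el.text = content


def _label_width(label: str, cfg: RenderConfig) -> float:
    return len(label) * cfg.font_size * 0.62


def _legend_svg(
    parent: ET.Element,
    ids: _IdPool,
    layout: PlotLayout,
    x0: float,
    y0: float,
    cell_px: float,
    cfg: RenderConfig,
) -> None:
    legend = layout.legend
    g = ET.SubElement(parent, "g", {"id": ids.get("legend"), "class": "legend"})
    key = cell_px
    ET.SubElement(
        g,
        "rect",
        {
            "x": _fmt(x0),
            "y": _fmt(y0),
            "width": _fmt(key),
            "height": _fmt(key),
            "fill": "#ffffff",
            "stroke": "#555555",
            "stroke-width": "0.8",
        },
    )
    for lev, _slot, (u, v), color in legend.dot_key:
        ET.SubElement(
            g,
            "circle",
            {
                "class": "legend-pip",
                "cx": _fmt(x0 + u * key),
                "cy": _fmt(y0 + (1.0 - v) * key),
                "r": _fmt(layout.style.dot_radius_frac * key),
                "fill": color,
                "data-level": lev,
            },
        )
        _text(g, x0 + key + 6, y0 + (1.0 - v) * key + cfg.font_size * 0.35, lev, cfg)
    y = y0 + key + cfg.font_size
    if legend.bg_key:
        for group, swatch in legend.bg_key:
            ET.SubElement(
                g,
                "rect",
                {
                    "class": "legend-bg",
                    "x": _fmt(x0),
                    "y": _fmt(y),
                    "width": _fmt(cfg.font_size),
                    "height": _fmt(cfg.font_size),
                    "fill": swatch,
                    "fill-opacity": _fmt(layout.style.bg_alpha),
                    "stroke": "#555555",
                    "stroke-width": "0.5",
                },
            )
            _text(g, x0 + cfg.font_size + 5, y + cfg.font_size * 0.85, group, cfg)
            y += cfg.font_size + 4
        y += cfg.font_size * 0.5
    if legend.color_ramp:
        ramp_w, ramp_h, n = key * 1.6, cfg.font_size * 0.8, 32
        lo, hi = legend.color_ramp["domain"]
        from .scales import ColorScale

        cs = layout.scales.color if layout.scales else ColorScale(vmax=max(abs(lo), hi))
        for i in range(n):
            val = lo + (i + 0.5) / n * (hi - lo)
            ET.SubElement(
                g,
                "rect",
                {
                    "class": "legend-ramp",
                    "x": _fmt(x0 + i * ramp_w / n),
                    "y": _fmt(y),
                    "width": _fmt(ramp_w / n + 0.1),
                    "height": _fmt(ramp_h),
                    "fill": cs(val),
                },
            )
        mid_x = x0 + (0.0 - lo) / (hi - lo) * ramp_w
        ET.SubElement(
            g,
            "line",
            {
                "class": "legend-midtick",
                "x1": _fmt(mid_x),
                "y1": _fmt(y),
                "x2": _fmt(mid_x),
                "y2": _fmt(y + ramp_h + 3),
                "stroke": "#222222",
                "stroke-width": "1",
            },
        )
        _text(g, x0, y + ramp_h + cfg.font_size, _fmt(lo), cfg)
        _text(g, mid_x - cfg.font_size * 0.3, y + ramp_h + cfg.font_size, "0", cfg)
        _text(g, x0 + ramp_w - cfg.font_size, y + ramp_h + cfg.font_size, _fmt(hi), cfg)
        y += ramp_h + cfg.font_size * 2
    if legend.size_ladder:
        cx = x0 + key * 0.2
        for val, r_frac in legend.size_ladder:
            r = r_frac * cell_px
            ET.SubElement(
                g,
                "circle",
                {
                    "class": "legend-size",
                    "cx": _fmt(cx),
                    "cy": _fmt(y + cell_px * 0.15),
                    "r": _fmt(r),
                    "fill": "#888888",
                },
            )
            _text(g, cx + cell_px * 0.25, y + cell_px * 0.15 + cfg.font_size * 0.35, _fmt(val), cfg)
            y += max(2 * r + 4, cfg.font_size + 4)


def _render_grid_svg(layout: PlotLayout, cfg: RenderConfig) -> str:
    cell_px = layout.style.cell_px * cfg.px_scale
    rows, cols = layout.row_order.labels, layout.col_order.labels
    row_w = max((_label_width(r, cfg) for r in rows), default=0.0) + 8
    rotate_cols = any(_label_width(c, cfg) > cell_px for c in cols)
    col_h = (
        max((_label_width(c, cfg) for c in cols), default=0.0) * 0.75 + 8
        if rotate_cols
        else cfg.font_size + 8
    )
    legend_w = (cell_px * 2.2 + cfg.font_size * 8) if cfg.show_legend else 0.0
    width = cfg.margin * 2 + row_w + len(cols) * cell_px + legend_w
    height = cfg.margin * 2 + col_h + max(len(rows) * cell_px, cell_px * 3 if cfg.show_legend else 0)

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": _fmt(width),
            "height": _fmt(height),
            "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
        },
    )
    ids = _IdPool()
    gx0, gy0 = cfg.margin + row_w, cfg.margin + col_h

    labels_g = ET.SubElement(svg, "g", {"id": ids.get("axis-labels"), "class": "axis-labels"})
    for i, r in enumerate(rows):
        _text(
            labels_g,
            gx0 - 6,
            gy0 + (i + 0.5) * cell_px + cfg.font_size * 0.35,
            r,
            cfg,
            **{"text-anchor": "end"},
        )
    for j, c in enumerate(cols):
        x = gx0 + (j + 0.5) * cell_px
        if rotate_cols:
            _text(
                labels_g,
                x,
                gy0 - 5,
                c,
                cfg,
                **{"text-anchor": "start", "transform": f"rotate(-45 {_fmt(x)} {_fmt(gy0 - 5)})"},
            )
        else:
            _text(labels_g, x, gy0 - 5, c, cfg, **{"text-anchor": "middle"})

    pos = {(cell.row_label, cell.col_label): cell for cell in layout.cells}
    for (r, c), cell in sorted(pos.items(), key=lambda kv: layout.grid_position(*kv[0])):
        i, j = layout.grid_position(r, c)
        _die_group(svg, ids, layout, cell, gx0 + j * cell_px, gy0 + i * cell_px, cell_px)

    if cfg.show_legend:
        _legend_svg(svg, ids, layout, gx0 + len(cols) * cell_px + cell_px * 0.5, gy0, cell_px, cfg)
    return ET.tostring(svg, encoding="unicode")


def _render_geo_svg(geo: GeoLayout, cfg: RenderConfig) -> str:
    layout = geo.base
    cell_px = layout.style.cell_px * cfg.px_scale
    lon0, lat0, lon1, lat1 = geo.viewport
    map_w = cfg.map_width_px * cfg.px_scale
    map_h = map_w * (lat1 - lat0) / (lon1 - lon0)
    legend_w = (cell_px * 2.2 + cfg.font_size * 8) if cfg.show_legend else 0.0
    width = cfg.margin * 2 + map_w + legend_w
    height = cfg.margin * 2 + max(map_h, cell_px * 3 if cfg.show_legend else 0)

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": _fmt(width),
            "height": _fmt(height),
            "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
        },
    )
    ids = _IdPool()
    ox, oy = cfg.margin, cfg.margin

    outlines_g = ET.SubElement(svg, "g", {"id": ids.get("outlines"), "class": "outlines"})
    for poly in geo.outlines:
        for ring in poly:
            pts = " ".join(
                f"{_fmt(ox + x)},{_fmt(oy + y)}"
                for x, y in (project(lon, lat, geo.viewport, map_w, map_h) for lon, lat in ring)
            )
            ET.SubElement(
                outlines_g,
                "polyline",
                {"points": pts, "fill": "none", "stroke": "#999999", "stroke-width": "0.8"},
            )

    cells = {c.row_label: c for c in layout.cells}
    for loc in layout.row_order.labels:
        if loc not in cells:
            continue
        p = geo.placements[loc]
        x, y = project(p.lon, p.lat, geo.viewport, map_w, map_h)
        edge = cell_px * p.glyph_scale
        _die_group(svg, ids, layout, cells[loc], ox + x - edge / 2, oy + y - edge / 2, edge)
        _text(
            svg,
            ox + x,
            oy + y + edge / 2 + cfg.font_size,
            loc,
            cfg,
            **{"text-anchor": "middle", "class": "geo-label"},
        )

    if cfg.show_legend:
        _legend_svg(svg, ids, layout, ox + map_w + cell_px * 0.5, oy, cell_px, cfg)
    return ET.tostring(svg, encoding="unicode")


def render_svg(layout: PlotLayout | GeoLayout, config: RenderConfig | None = None) -> str:
    """Render a layout to an SVG 1.1 document string.

    Deterministic: the same layout renders to byte-identical text.  Grid
    pips are ``circle.pip`` elements carrying ``data-level`` (and, for
    dominoes, ``data-split``) attributes; legend artwork uses distinct
    ``legend-*`` classes so pip counts stay unambiguous.
    """
    cfg = config or RenderConfig()
    if isinstance(layout, GeoLayout):
        return _render_geo_svg(layout, cfg)
    return _render_grid_svg(layout, cfg)
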