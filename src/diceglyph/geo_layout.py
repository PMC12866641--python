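"""Dice glyphs anchored at geographic coordinates.

The map mode reuses dice semantics — one die per *location*, pips marking
which levels of the dot variable occur there — but places each die at a
user-supplied longitude/latitude anchor instead of a grid position,
optionally over region outlines read from GeoJSON.  Projection is plain
equirectangular (degrees map linearly to pixels, north up), which is
monotone in both axes and adequate for glyph overlays; no de-collision is
attempted — overlapping anchors are drawn as given with a logged warning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .data_model import LongTable, presence_matrix
from .dice_layout import DiceCell, PlotLayout, PlotStyle, background_fill, categorical_colors
from .errors import BadCoordinate, DiceGlyphError, MissingPlacement
from .legend import build_legend
from .ordering import AxisOrder
from .pip_geometry import assign_slots

#: Placeholder column label for the degenerate single-column geo grid.
GEO_COL = "geo"


@dataclass(frozen=True)
class GeoPlacement:
    """Anchor for one die: location label plus lon/lat in degrees."""

    die_id: str
    lon: float
    lat: float
    glyph_scale: float = 1.0

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise BadCoordinate(f"longitude {self.lon} for {self.die_id!r} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise BadCoordinate(f"latitude {self.lat} for {self.die_id!r} outside [-90, 90]")


@dataclass
class GeoLayout:
    """A dice layout plus one anchor per die and optional outlines.

    ``viewport`` is (lon_min, lat_min, lon_max, lat_max); ``outlines`` is a
    list of polygons, each a list of rings, each a list of (lon, lat)."""

    base: PlotLayout
    placements: dict[str, GeoPlacement]
    outlines: list[list[list[tuple[float, float]]]] = field(default_factory=list)
    projection: str = "equirectangular"
    viewport: tuple[float, float, float, float] = (-180.0, -90.0, 180.0, 90.0)

    @property
    def log(self) -> list[str]:
        return self.base.log


def project(
    lon: float,
    lat: float,
    viewport: tuple[float, float, float, float],
    width: float,
    height: float,
) -> tuple[float, float]:
    """Equirectangular projection into a width x height pixel box, north up."""
    lon0, lat0, lon1, lat1 = viewport
    x = (lon - lon0) / (lon1 - lon0) * width
    y = (lat1 - lat) / (lat1 - lat0) * height
    return (x, y)


def _auto_viewport(
    placements: Sequence[GeoPlacement],
    outlines: list[list[list[tuple[float, float]]]],
    pad_frac: float = 0.08,
) -> tuple[float, float, float, float]:
    lons = [p.lon for p in placements]
    lats = [p.lat for p in placements]
    for poly in outlines:
        for ring in poly:
            lons.extend(pt[0] for pt in ring)
            lats.extend(pt[1] for pt in ring)
    lon0, lon1 = min(lons), max(lons)
    lat0, lat1 = min(lats), max(lats)
    pad_lon = (lon1 - lon0) * pad_frac or 1.0
    pad_lat = (lat1 - lat0) * pad_frac or 1.0
    return (lon0 - pad_lon, lat0 - pad_lat, lon1 + pad_lon, lat1 + pad_lat)


def place_dice_on_map(
    table: LongTable,
    placements: Sequence[GeoPlacement] | Mapping[str, tuple[float, float]],
    outlines: list | None = None,
    style: PlotStyle | None = None,
    viewport: tuple[float, float, float, float] | None = None,
) -> GeoLayout:
    """Place one die per location label at its geographic anchor.

    The table is a validated dice-mode table whose row variable is the
    location; pip patterns are the marginal presence profiles, so a
    location's die is exactly the die the same records would produce in a
    single-column dice grid.
    """
    if table.mode != "dice":
        raise DiceGlyphError("map mode needs a dice-mode table (row variable = location)")
    style = style or PlotStyle()
    if isinstance(placements, Mapping):
        placements = [GeoPlacement(str(k), float(v[0]), float(v[1])) for k, v in placements.items()]
    by_id: dict[str, GeoPlacement] = {}
    for p in placements:
        if p.die_id in by_id:
            raise DiceGlyphError(f"duplicate placement for location {p.die_id!r}")
        by_id[p.die_id] = p

    locations = table.levels("row")
    missing = [loc for loc in locations if loc not in by_id]
    if missing:
        raise MissingPlacement(f"location(s) without coordinates: {missing}")

    log: list[str] = []
    coord_seen: dict[tuple[float, float], str] = {}
    for loc in locations:
        p = by_id[loc]
        key = (p.lon, p.lat)
        if key in coord_seen:
            log.append(f"locations {coord_seen[key]!r} and {loc!r} share anchor {key}; glyphs overlap")
        else:
            coord_seen[key] = loc

    slot_map = assign_slots(table.dot_levels, variant=style.variant, mirror=style.mirror)
    pm = presence_matrix(table, "row")
    bg_levels = table.level_registry.get("bg", [])
    show_bg = style.show_background if style.show_background is not None else True
    bg_colors = categorical_colors(bg_levels, style.bg_palette, log) if (bg_levels and show_bg) else {}
    dot_colors = categorical_colors(table.dot_levels, style.dot_palette, log)

    bg_by_loc: dict[str, str] = {}
    if table.roles.bg_var:
        for _, rec in table.records.iterrows():
            loc = rec[table.roles.row_var]
            grp = rec[table.roles.bg_var]
            if bg_by_loc.setdefault(loc, grp) != grp:
                raise DiceGlyphError(
                    f"location {loc!r} maps to multiple background groups"
                )

    cells = []
    for i, loc in enumerate(locations):
        present = tuple(int(k) for k in pm.profile[i].nonzero()[0])
        if present or style.draw_empty:
            cells.append(DiceCell(loc, GEO_COL, present, bg_group=bg_by_loc.get(loc)))
    cells = background_fill(cells, bg_colors, style.neutral_fill)

    base = PlotLayout(
        mode="geo-dice",
        slot_map=slot_map,
        row_order=AxisOrder(axis="row", labels=tuple(locations), method="as-is"),
        col_order=AxisOrder(axis="col", labels=(GEO_COL,), method="as-is"),
        cells=cells,
        style=style,
        dot_colors=dot_colors,
        bg_colors=bg_colors,
        legend=build_legend(slot_map, dot_colors, bg_colors or None),
        log=log,
    )
    outlines = outlines or []
    used = {by_id[loc] for loc in locations}
    vp = viewport or _auto_viewport(sorted(used, key=lambda p: p.die_id), outlines)
    return GeoLayout(base=base, placements={loc: by_id[loc] for loc in locations},
                     outlines=outlines, viewport=vp)


def read_placements_csv(path: str | Path, sep: str | None = None) -> list[GeoPlacement]:
    """Read (location, lon, lat[, glyph_scale]) anchors from CSV/TSV."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    loc_col = next((cols[k] for k in ("location", "die_id", "id", "label") if k in cols), df.columns[0])
    if "lon" not in cols or "lat" not in cols:
        raise DiceGlyphError(f"placement file {path} needs 'lon' and 'lat' columns")
    out = []
    for _, r in df.iterrows():
        scale = float(r[cols["glyph_scale"]]) if "glyph_scale" in cols else 1.0
        out.append(GeoPlacement(str(r[loc_col]), float(r[cols["lon"]]), float(r[cols["lat"]]), scale))
    return out


def read_geojson_outlines(source: str | Path | dict) -> list[list[list[tuple[float, float]]]]:
    """Extract polygon outlines from a GeoJSON FeatureCollection.

    Returns a list of polygons (Polygon features directly, MultiPolygon
    parts flattened), each a list of rings of (lon, lat) pairs.  Other
    geometry types are ignored.
    """
    if isinstance(source, (str, Path)):
        obj = json.loads(Path(source).read_text())
    else:
        obj = source
    if obj.get("type") == "FeatureCollection":
        geoms = [f.get("geometry") or {} for f in obj.get("features", [])]
    elif obj.get("type") == "Feature":
        geoms = [obj.get("geometry") or {}]
    else:
        geoms = [obj]
    polys: list[list[list[tuple[float, float]]]] = []
    for g in geoms:
        if g.get("type") == "Polygon":
            polys.append([[(float(x), float(y)) for x, y in ring] for ring in g["coordinates"]])
        elif g.get("type") == "MultiPolygon":
            for part in g["coordinates"]:
                polys.append([[(float(x), float(y)) for x, y in ring] for ring in part])
    return polys


def polygon_centroid(polygon: list[list[tuple[float, float]]]) -> tuple[float, float]:
    """Centroid of a polygon's largest ring — a convenience for deriving
    anchors from region outlines (anchors remain user-supplied inputs)."""
    from shapely.geometry import Polygon

    largest = max((Polygon(ring) for ring in polygon if len(ring) >= 3), key=lambda p: p.area)
    c = largest.centroid
    return (float(c.x), float(c.y))
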