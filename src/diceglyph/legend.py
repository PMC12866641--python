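"""Legend construction: the miniature die key, background swatches, scales.

The legend's miniature die shows one labeled pip per *observed* level at
exactly the slot coordinate the plot uses, so a reader can map any pip in
any die back to its category.  Background swatches list the group ->
fill-color pairing; domino legends add a diverging color ramp with a
midpoint tick at zero and a size ladder with value labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pip_geometry import SlotMap
from .scales import ContinuousScales


@dataclass(frozen=True)
class LegendSpec:
    """Backend-independent legend description.

    dot_key
        One entry per level: (level, slot index, (u, v), fill color), in
        slot order; coordinates equal the plot's SlotMap coordinates.
    bg_key
        Optional (group, swatch color) pairs.
    color_ramp
        Optional dict with the diverging ramp's domain, midpoint and
        sampled color stops.
    size_ladder
        Optional (value, radius) rungs for the size channel.
    """

    dot_key: tuple[tuple[str, int, tuple[float, float], str], ...]
    bg_key: tuple[tuple[str, str], ...] | None = None
    color_ramp: dict | None = None
    size_ladder: tuple[tuple[float, float], ...] | None = None


def build_legend(
    slot_map: SlotMap,
    dot_colors: dict[str, str],
    bg_colors: dict[str, str] | None = None,
    scales: ContinuousScales | None = None,
) -> LegendSpec:
    """Assemble the legend for one plot.

    Pip coordinates in the dot key are taken verbatim from ``slot_map`` so
    the key die is congruent with every die in the grid.
    """
    dot_key = tuple(
        (lev, slot_map.assignment[lev], slot_map.coord_of(lev), dot_colors[lev])
        for lev in slot_map.dot_levels
    )
    bg_key = tuple(sorted(bg_colors.items())) if bg_colors else None

    color_ramp = None
    size_ladder = None
    if scales is not None:
        m = scales.color.vmax
        stops = tuple(
            (round(-m + t * 2 * m, 6), scales.color(-m + t * 2 * m))
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        )
        color_ramp = {
            "domain": (round(-m, 6), round(m, 6)),
            "midpoint": 0.0,
            "midpoint_color": scales.color.midpoint_color,
            "palette": scales.color.palette,
            "stops": stops,
        }
        vmax = scales.size.vmax
        rungs = (0.0, vmax / 2.0, vmax) if vmax > 0 else (0.0,)
        size_ladder = tuple((round(v, 6), round(scales.size(v), 6)) for v in rungs)

    return LegendSpec(
        dot_key=dot_key, bg_key=bg_key, color_ramp=color_ramp, size_ladder=size_ladder
    )
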