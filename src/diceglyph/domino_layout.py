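"""Assemble the domino-plot specification.

A domino plot extends the dice grid for multi-contrast comparisons: pip
slots carry the *contrasts* (e.g. five disease-vs-control tests), each tile
splits into two halves for a binary variable (e.g. sex), and every pip
carries two continuous channels — color for the signed effect size (log2
fold change) on a diverging ramp anchored at zero, and size for a
nonnegative significance score.  This shows what a panel of volcano plots
would, for a hand-picked gene set, in a single matrix.

Background coloring is off by default here (it crowds the tile), but can be
switched back on via ``PlotStyle(show_background=True)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .data_model import LongTable
from .dice_layout import (
    PlotLayout,
    PlotStyle,
    background_fill,
    categorical_colors,
)
from .errors import DiceGlyphError
from .legend import build_legend
from .ordering import resolve_axis_order
from .pip_geometry import assign_slots
from .scales import ContinuousScales, color_scale, size_scale

# Re-exported: the continuous channels live in .scales.
__all__ = [
    "DominoDot",
    "HalfTile",
    "DominoCell",
    "build_domino_layout",
    "color_scale",
    "size_scale",
    "ContinuousScales",
]


@dataclass(frozen=True)
class DominoDot:
    """One value-carrying pip: slot index, effect size, significance.

    ``tested=False`` marks a record that exists but has no finite values
    ("tested, no result"); it renders as a hollow minimum-size pip.  A
    missing (contrast, half) combination draws no pip at all.
    """

    slot: int
    color_value: float
    size_value: float
    tested: bool


@dataclass(frozen=True)
class HalfTile:
    """One half of a domino tile, bound to one split level."""

    split_level: str
    dots: tuple[DominoDot, ...]


@dataclass
class DominoCell:
    """One domino tile: exactly the halves of the split-level registry,
    in registry order (the first split level is always the left/top half)."""

    row_label: str
    col_label: str
    halves: tuple[HalfTile, ...]
    bg_group: str | None = None
    fill: str = "#ffffff"

    # Duck-type compatibility with DiceCell for shared grid helpers.
    @property
    def present_slots(self) -> tuple[int, ...]:
        return tuple(sorted({d.slot for h in self.halves for d in h.dots}))


def _finite(x) -> bool:
    return x is not None and isinstance(x, (int, float)) and math.isfinite(x)


def build_domino_layout(
    table: LongTable,
    order_spec: Mapping[str, object] | None = None,
    style: PlotStyle | None = None,
    color_vmax: float | None = None,
) -> PlotLayout:
    """Build the full domino layout from a validated domino-mode table.

    The slot map is built over the contrast levels; each observed
    (row, col) yields one tile with one half per split level (both halves
    always present, possibly dot-free).  If no split variable was declared
    the tile degenerates to a single half — a dice plot with value-carrying
    pips.  ``color_vmax`` overrides the symmetric color domain half-width.
    """
    if table.mode != "domino":
        raise DiceGlyphError(
            f"build_domino_layout needs a domino-mode table, got {table.mode!r}"
        )
    style = style or PlotStyle()
    order_spec = dict(order_spec or {})
    log: list[str] = []
    roles = table.roles

    slot_map = assign_slots(table.dot_levels, variant=style.variant, mirror=style.mirror)
    row_order = resolve_axis_order(table, "row", order_spec.get("row", "as-is"))
    col_order = resolve_axis_order(table, "col", order_spec.get("col", "as-is"))

    split_levels = tuple(table.level_registry["split"]) if roles.split_var else ("all",)

    # (row, col, split) -> {slot: (color, size, tested)}; first record wins.
    per_half: dict[tuple[str, str, str], dict[int, tuple[float, float, bool]]] = {}
    positions: list[tuple[str, str]] = []
    seen_pos: set[tuple[str, str]] = set()
    bg_by_pos: dict[tuple[str, str], str] = {}
    for _, rec in table.records.iterrows():
        pos = (rec[roles.row_var], rec[roles.col_var])
        if pos not in seen_pos:
            seen_pos.add(pos)
            positions.append(pos)
        split = rec[roles.split_var] if roles.split_var else "all"
        slot = slot_map.assignment[rec[roles.contrast_var]]
        cval = float(rec[roles.color_var])
        sval = float(rec[roles.size_var])
        bucket = per_half.setdefault((*pos, split), {})
        if slot in bucket:
            log.append(f"dropped extra record for cell {pos}, split {split!r}, slot {slot}")
            continue
        bucket[slot] = (cval, sval, _finite(cval) and _finite(sval))
        if roles.bg_var:
            bg_by_pos.setdefault(pos, rec[roles.bg_var])

    all_colors = [v[0] for b in per_half.values() for v in b.values() if _finite(v[0])]
    all_sizes = [v[1] for b in per_half.values() for v in b.values() if _finite(v[1])]
    scales = ContinuousScales(
        color=color_scale(all_colors, palette=style.diverging_palette, vmax=color_vmax),
        size=size_scale(all_sizes, encoding=style.size_encoding),
    )

    cells = []
    for r in row_order.labels:
        for c in col_order.labels:
            pos = (r, c)
            if pos not in seen_pos:
                continue
            halves = []
            for split in split_levels:
                bucket = per_half.get((*pos, split), {})
                dots = tuple(
                    DominoDot(slot, *bucket[slot]) for slot in sorted(bucket)
                )
                halves.append(HalfTile(split_level=split, dots=dots))
            cells.append(DominoCell(r, c, halves=tuple(halves), bg_group=bg_by_pos.get(pos)))

    show_bg = style.show_background if style.show_background is not None else False
    bg_levels = table.level_registry.get("bg", [])
    bg_colors = categorical_colors(bg_levels, style.bg_palette, log) if (bg_levels and show_bg) else {}
    cells = background_fill(cells, bg_colors, style.neutral_fill)

    # Pips are value-colored; the categorical dot key still names the
    # contrast each slot carries, using the neutral midpoint color.
    dot_colors = {lev: scales.color.midpoint_color for lev in slot_map.dot_levels}
    legend = build_legend(slot_map, dot_colors, bg_colors or None, scales)

    return PlotLayout(
        mode="domino",
        slot_map=slot_map,
        row_order=row_order,
        col_order=col_order,
        cells=cells,
        style=style,
        dot_colors=dot_colors,
        bg_colors=bg_colors,
        legend=legend,
        scales=scales,
        log=log,
    )
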