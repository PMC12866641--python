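"""Assemble the dice-plot geometric specification.

A dice plot is a grid: rows and columns are two categorical variables, and
each occupied (row, column) cell is a die face whose pips mark which levels
of a third categorical variable occur in that subset.  An optional fourth
variable colors the die background to flag higher-level groupings.  The
output :class:`PlotLayout` is backend-independent: renderers and tests
consume it (or its JSON export) without re-deriving any geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .data_model import LongTable
from .errors import ConflictingBackground, DiceGlyphError
from .legend import LegendSpec, build_legend
from .ordering import AxisOrder, resolve_axis_order
from .pip_geometry import SlotMap, assign_slots
from .scales import DIVERGING_PALETTE, ContinuousScales

#: Default categorical palette (tab10 vocabulary), cycled when more groups
#: than colors are observed.
CATEGORICAL_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

NEUTRAL_FILL = "#ffffff"


@dataclass(frozen=True)
class PlotStyle:
    """Tunable appearance parameters, all backend-independent.

    ``cell_px`` is the die edge in pixels; ``dot_radius_frac`` the pip
    radius as a fraction of the cell edge; ``bg_alpha`` keeps pips legible
    over filled backgrounds.  ``split_orientation`` applies to domino
    tiles (``"vertical"`` = left|right halves, ``"horizontal"`` =
    top|bottom).
    """

    cell_px: float = 40.0
    dot_radius_frac: float = 0.12
    bg_alpha: float = 0.35
    variant: str = "standard"
    mirror: bool = False
    draw_empty: bool = False
    split_orientation: str = "vertical"
    size_encoding: str = "radius"
    diverging_palette: str = DIVERGING_PALETTE
    dot_palette: Mapping[str, str] | None = None
    bg_palette: Mapping[str, str] | None = None
    neutral_fill: str = NEUTRAL_FILL
    show_background: bool | None = None  # None = mode default

    def __post_init__(self) -> None:
        if self.cell_px <= 0 or self.dot_radius_frac <= 0:
            raise DiceGlyphError("cell_px and dot_radius_frac must be positive")
        if not 0 <= self.bg_alpha <= 1:
            raise DiceGlyphError("bg_alpha must lie in [0, 1]")
        if self.split_orientation not in ("vertical", "horizontal"):
            raise DiceGlyphError(
                f"split_orientation must be 'vertical' or 'horizontal', "
                f"got {self.split_orientation!r}"
            )


@dataclass
class DiceCell:
    """One die: which pip slots are present plus background styling."""

    row_label: str
    col_label: str
    present_slots: tuple[int, ...]
    bg_group: str | None = None
    fill: str = NEUTRAL_FILL


@dataclass
class PlotLayout:
    """Complete backend-independent plot specification.

    The slot map is global: every cell (and the legend's key die) uses the
    same level -> coordinate assignment, which is the property that makes
    dice comparable across the grid.
    """

    mode: str
    slot_map: SlotMap
    row_order: AxisOrder
    col_order: AxisOrder
    cells: list
    style: PlotStyle
    dot_colors: dict[str, str]
    bg_colors: dict[str, str]
    legend: LegendSpec
    scales: ContinuousScales | None = None
    log: list[str] = field(default_factory=list)

    def grid_position(self, row_label: str, col_label: str) -> tuple[int, int]:
        """(row index, col index); rows grow downward, columns rightward."""
        return (
            self.row_order.labels.index(row_label),
            self.col_order.labels.index(col_label),
        )


def categorical_colors(
    levels: Sequence[str],
    overrides: Mapping[str, str] | None = None,
    log: list[str] | None = None,
) -> dict[str, str]:
    """Assign one color per level; user overrides win, the rest cycle the
    default palette (auto-extension is logged, never an error)."""
    overrides = dict(overrides or {})
    out: dict[str, str] = {}
    auto = 0
    for lev in levels:
        if lev in overrides:
            out[lev] = overrides[lev]
        else:
            out[lev] = CATEGORICAL_PALETTE[auto % len(CATEGORICAL_PALETTE)]
            if overrides and log is not None:
                log.append(f"auto-assigned color for level {lev!r} missing from palette")
            auto += 1
    return out


def background_fill(
    cells: Sequence[DiceCell],
    bg_colors: Mapping[str, str],
    neutral: str = NEUTRAL_FILL,
) -> list[DiceCell]:
    """Return cells with fill resolved from their background group."""
    return [
        replace(c, fill=bg_colors.get(c.bg_group, neutral) if c.bg_group else neutral)
        for c in cells
    ]


def _collect_cells(table: LongTable) -> tuple[dict, dict]:
    """Group records into (row, col) -> present dot-level set, bg group."""
    roles = table.roles
    slots_by_pos: dict[tuple[str, str], set[str]] = {}
    bg_by_pos: dict[tuple[str, str], set[str]] = {}
    bg_col = roles.bg_var
    for _, rec in table.records.iterrows():
        pos = (rec[roles.row_var], rec[roles.col_var])
        slots_by_pos.setdefault(pos, set()).add(rec[roles.dot_var])
        if bg_col is not None:
            bg_by_pos.setdefault(pos, set()).add(rec[bg_col])
    conflicts = {pos: sorted(v) for pos, v in bg_by_pos.items() if len(v) > 1}
    if conflicts:
        listing = "; ".join(f"{pos} -> {groups}" for pos, groups in sorted(conflicts.items()))
        raise ConflictingBackground(
            f"grid position(s) map to multiple background groups: {listing}"
        )
    bg_single = {pos: next(iter(v)) for pos, v in bg_by_pos.items()}
    return slots_by_pos, bg_single


def build_dice_layout(
    table: LongTable,
    order_spec: Mapping[str, object] | None = None,
    style: PlotStyle | None = None,
) -> PlotLayout:
    """Build the full dice-plot layout from a validated table.

    Parameters
    ----------
    table
        Output of :func:`diceglyph.data_model.validate_table` (dice mode).
    order_spec
        Optional ``{"row": spec, "col": spec}`` with each spec ``"as-is"``,
        ``"cluster"`` or an explicit label list.
    style
        Appearance overrides; defaults are sensible for <= 30 columns.
    """
    if table.mode != "dice":
        raise DiceGlyphError(f"build_dice_layout needs a dice-mode table, got {table.mode!r}")
    style = style or PlotStyle()
    order_spec = dict(order_spec or {})
    log: list[str] = []

    slot_map = assign_slots(table.dot_levels, variant=style.variant, mirror=style.mirror)
    row_order = resolve_axis_order(table, "row", order_spec.get("row", "as-is"))
    col_order = resolve_axis_order(table, "col", order_spec.get("col", "as-is"))

    slots_by_pos, bg_by_pos = _collect_cells(table)
    show_bg = style.show_background if style.show_background is not None else True
    bg_levels = table.level_registry.get("bg", [])
    bg_colors = (
        categorical_colors(bg_levels, style.bg_palette, log) if (bg_levels and show_bg) else {}
    )
    dot_colors = categorical_colors(table.dot_levels, style.dot_palette, log)

    cells = []
    for r in row_order.labels:
        for c in col_order.labels:
            pos = (r, c)
            if pos in slots_by_pos:
                present = tuple(sorted(slot_map.assignment[lev] for lev in slots_by_pos[pos]))
                cells.append(DiceCell(r, c, present, bg_group=bg_by_pos.get(pos)))
            elif style.draw_empty:
                cells.append(DiceCell(r, c, ()))
    cells = background_fill(cells, bg_colors, style.neutral_fill)

    legend = build_legend(slot_map, dot_colors, bg_colors or None)
    return PlotLayout(
        mode="dice",
        slot_map=slot_map,
        row_order=row_order,
        col_order=col_order,
        cells=cells,
        style=style,
        dot_colors=dot_colors,
        bg_colors=bg_colors,
        legend=legend,
        log=log,
    )
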