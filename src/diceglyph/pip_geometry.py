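"""Fixed pip-slot coordinates for die faces of one to six pips.

Pip positions follow the traditional die-face patterns, drawn from a single
seven-anchor vocabulary on the unit cell: four corners at 0.2/0.8, two edge
midpoints at (0.2, 0.5)/(0.8, 0.5), and the center (0.5, 0.5).  The v axis
points up (mathematical convention); renderers flip as needed.  A
``triangle3`` variant replaces the three-pip diagonal with an equilateral,
vertex-up triangle for extra clarity.

Every level of the pip-bearing categorical variable is assigned one slot,
and that assignment is global: the same level occupies the same coordinate
in every die of a plot, which is what makes dice comparable at a glance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import OutOfRange, TooManyLevels, VariantMismatch

_LO, _MID, _HI = 0.2, 0.5, 0.8

# Anchor vocabulary (u, v), v up.
_TL = (_LO, _HI)
_TR = (_HI, _HI)
_ML = (_LO, _MID)
_MR = (_HI, _MID)
_BL = (_LO, _LO)
_BR = (_HI, _LO)
_C = (_MID, _MID)

# Canonical slot order per face.  The 2- and 3-pip diagonals run
# bottom-left -> top-right; ``mirror=True`` reflects u to flip them.
_FACES: dict[int, tuple[tuple[float, float], ...]] = {
    1: (_C,),
    2: (_BL, _TR),
    3: (_BL, _C, _TR),
    4: (_TL, _TR, _BL, _BR),
    5: (_TL, _TR, _C, _BL, _BR),
    6: (_TL, _TR, _ML, _MR, _BL, _BR),
}

#: Circumradius of the triangle3 variant about the cell center.
TRIANGLE3_CIRCUMRADIUS = 0.3


def _triangle3_coords() -> tuple[tuple[float, float], ...]:
    # Equilateral, vertex-up: apex, then lower-left, lower-right.
    import math

    r = TRIANGLE3_CIRCUMRADIUS
    out = []
    for deg in (90.0, 210.0, 330.0):
        rad = math.radians(deg)
        out.append((0.5 + r * math.cos(rad), 0.5 + r * math.sin(rad)))
    return tuple((round(u, 6), round(v, 6)) for u, v in out)


@dataclass(frozen=True)
class PipLayout:
    """Ordered pip coordinates for one die face."""

    n_slots: int
    variant: str
    coords: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class SlotMap:
    """Global, immutable level -> slot assignment for one plot.

    ``assignment`` is a bijection from pip-variable levels to slot indices
    of ``layout.coords``; it is identical across every die of the plot.
    """

    dot_levels: tuple[str, ...]
    layout: PipLayout
    assignment: dict[str, int]

    def coord_of(self, level: str) -> tuple[float, float]:
        return self.layout.coords[self.assignment[level]]


def pip_coordinates(n: int, variant: str = "standard", mirror: bool = False) -> PipLayout:
    """Canonical pip coordinates for an ``n``-pip die face.

    Parameters
    ----------
    n
        Number of pips, 1..6.
    variant
        ``"standard"`` (traditional face patterns) or ``"triangle3"``
        (equilateral triangle; only valid for ``n == 3``).
    mirror
        Reflect u -> 1 - u, flipping the 2-/3-pip diagonal direction.
    """
    if not isinstance(n, int) or isinstance(n, bool):
        raise OutOfRange(f"pip count must be an integer, got {n!r}")
    if n < 1 or n > 6:
        raise OutOfRange(f"pip count {n} outside the supported range 1..6")
    if variant == "triangle3":
        if n != 3:
            raise VariantMismatch(f"triangle3 variant requires n=3, got n={n}")
        coords = _triangle3_coords()
    elif variant == "standard":
        coords = _FACES[n]
    else:
        raise VariantMismatch(f"unknown variant {variant!r}")
    if mirror:
        coords = tuple((round(1.0 - u, 6), v) for u, v in coords)
    return PipLayout(n_slots=n, variant=variant, coords=coords)


def assign_slots(
    dot_levels, variant: str = "standard", mirror: bool = False
) -> SlotMap:
    """Assign each level (in registry order) to a pip slot.

    A pure function of the ordered level list: level i maps to slot i of
    :func:`pip_coordinates` for the matching face.  The slot count equals
    the number of levels, so a four-level variable uses the four-corner
    face, not a sparse six-pip grid.
    """
    levels = tuple(str(x) for x in dot_levels)
    if len(levels) < 1 or len(levels) > 6:
        raise TooManyLevels(
            f"{len(levels)} dot levels outside the supported range 1..6: "
            f"{list(levels)}"
        )
    if len(set(levels)) != len(levels):
        raise TooManyLevels(f"dot levels must be distinct: {list(levels)}")
    layout = pip_coordinates(len(levels), variant=variant, mirror=mirror)
    return SlotMap(
        dot_levels=levels,
        layout=layout,
        assignment={lev: i for i, lev in enumerate(levels)},
    )
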