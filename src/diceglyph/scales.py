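"""Continuous color and size scales for value-carrying pips.

Domino plots map a signed effect size (conventionally a log2 fold change)
onto a diverging color ramp anchored at zero, and a nonnegative
significance score (conventionally -log10 adjusted p) onto pip radius.
The color domain is symmetric about zero — [-M, M] with M the largest
absolute finite value unless overridden — so that equal up- and
down-regulation get mirror colors and zero always hits the ramp's neutral
midpoint.  Values outside the domain clamp to the endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .errors import AllMissing, DiceGlyphError

#: Default pip radius bounds as fractions of the cell edge.
R_MIN_DEFAULT = 0.04
R_MAX_DEFAULT = 0.14

#: Default diverging ramp (blue = down, white = neutral, red = up).
DIVERGING_PALETTE = "RdBu_r"


@dataclass(frozen=True)
class ColorScale:
    """Diverging color map with a fixed midpoint at zero.

    ``vmax`` defines the symmetric domain [-vmax, vmax]; out-of-domain
    values clamp.  NaN (tested but missing) maps to a neutral grey.
    """

    vmax: float
    palette: str = DIVERGING_PALETTE
    na_color: str = "#b0b0b0"

    def __call__(self, value: float) -> str:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return self.na_color
        t = (float(value) + self.vmax) / (2.0 * self.vmax)
        t = min(max(t, 0.0), 1.0)
        return to_hex(colormaps[self.palette](t))

    @property
    def midpoint_color(self) -> str:
        return self(0.0)


@dataclass(frozen=True)
class SizeScale:
    """Monotone map from a nonnegative score to a pip radius.

    Linear in radius by default; ``encoding="area"`` makes pip *area*
    proportional to the score instead (radius grows with sqrt).  Values at
    or below zero get ``r_min``, at or above ``vmax`` get ``r_max``.
    """

    vmax: float
    r_min: float = R_MIN_DEFAULT
    r_max: float = R_MAX_DEFAULT
    encoding: str = "radius"

    def __call__(self, value: float) -> float:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return self.r_min
        t = min(max(float(value) / self.vmax, 0.0), 1.0) if self.vmax > 0 else 0.0
        if self.encoding == "area":
            lo, hi = self.r_min**2, self.r_max**2
            return math.sqrt(lo + t * (hi - lo))
        return self.r_min + t * (self.r_max - self.r_min)


@dataclass(frozen=True)
class ContinuousScales:
    """The pair of continuous channels a domino layout carries."""

    color: ColorScale
    size: SizeScale


def color_scale(values, palette: str = DIVERGING_PALETTE, vmax: float | None = None) -> ColorScale:
    """Build a diverging color scale over signed effect sizes.

    The domain is [-M, M] with M = max absolute finite value, or the user
    override.  A degenerate all-zero input widens to [-1, 1] so the map
    stays well defined.
    """
    if vmax is None:
        arr = np.asarray(list(values), dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size == 0:
            raise AllMissing("color scale requested but no finite effect values exist")
        vmax = float(np.max(np.abs(finite)))
    if vmax <= 0:
        vmax = 1.0
    return ColorScale(vmax=vmax, palette=palette)


def size_scale(
    values,
    r_min: float = R_MIN_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
    encoding: str = "radius",
    vmax: float | None = None,
) -> SizeScale:
    """Build a size scale over nonnegative significance scores.

    Linear from [0, max value] to [r_min, r_max]; untested pips are drawn
    at ``r_min`` with hollow styling by the renderer.
    """
    if not (0 < r_min <= r_max):
        raise DiceGlyphError(f"need 0 < r_min <= r_max, got {r_min}, {r_max}")
    if encoding not in ("radius", "area"):
        raise DiceGlyphError(f"unknown size encoding {encoding!r}")
    if vmax is None:
        arr = np.asarray(list(values), dtype=float)
        finite = arr[np.isfinite(arr)]
        vmax = float(np.max(finite)) if finite.size else 0.0
    return SizeScale(vmax=vmax, r_min=r_min, r_max=r_max, encoding=encoding)
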