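"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`DiceGlyphError` so the
CLI can map any validation problem to a single exit code and a one-line
``ErrorName: message`` report.
"""


class DiceGlyphError(Exception):
    """Base class for all diceglyph validation and layout errors."""

    @property
    def code(self) -> str:
        return type(self).__name__


class MissingColumn(DiceGlyphError):
    """A declared role column is absent from the input table."""


class TooManyLevels(DiceGlyphError):
    """A pip-bearing variable (dot or contrast) exceeds six levels."""


class EmptyInput(DiceGlyphError):
    """The input table holds zero records."""


class NonBinarySplit(DiceGlyphError):
    """The split variable does not have exactly two observed levels."""


class NonNumericValue(DiceGlyphError):
    """A continuous value column contains an unparseable entry."""


class OutOfRange(DiceGlyphError):
    """Requested pip count outside 1..6."""


class VariantMismatch(DiceGlyphError):
    """The triangular arrangement was requested for a count other than 3."""


class BadManualOrder(DiceGlyphError):
    """A manual axis order is not a permutation of the observed labels."""


class ConflictingBackground(DiceGlyphError):
    """One grid position maps to more than one background group."""


class MissingPlacement(DiceGlyphError):
    """A location in the table has no geographic anchor."""


class BadCoordinate(DiceGlyphError):
    """A longitude/latitude anchor lies outside valid bounds."""


class AllMissing(DiceGlyphError):
    """A continuous scale was requested but no finite values exist."""


class DegenerateConfig(DiceGlyphError):
    """A fixture configuration with zero genes, cell types or conditions."""
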