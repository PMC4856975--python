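"""Error taxonomy shared by all bundlekit modules.

Every domain error raised by the library derives from :class:`BundlekitError`
so the CLI can map them uniformly to exit code 1.
"""


class BundlekitError(Exception):
    """Base class for all bundlekit domain errors."""


class AlignmentShapeError(BundlekitError):
    """Rows of an alignment have unequal lengths, or the alignment is degenerate."""


class AlphabetError(BundlekitError):
    """A symbol is not part of the alphabet in use."""


class IdentityError(BundlekitError):
    """Sequence labels are duplicated or otherwise break identity assumptions."""


class BoundsError(BundlekitError):
    """A 1-based sequence or column index is out of range."""


class QuerySyntaxError(BundlekitError):
    """Selection query could not be parsed.

    Carries the character ``position`` (0-based) where parsing failed.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class GroupingError(BundlekitError):
    """Group assignment unusable for supervised analysis."""


class ModelError(BundlekitError):
    """A probabilistic model could not be built (e.g. no match states)."""


class NumericalError(BundlekitError):
    """A computation is undefined for the given parameters (e.g. zero emission)."""


class OrdinationError(BundlekitError):
    """Correspondence analysis cannot run on the given table."""


class ConfigurationError(BundlekitError):
    """An unknown named resource (ordering, substitution matrix) was requested."""


class InputError(BundlekitError):
    """Generic invalid-input error for operations without a finer category."""


class NewickParseError(BundlekitError):
    """Malformed Newick text; carries the failing character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class CapabilityError(BundlekitError):
    """A required optional capability (e.g. rasterizer) is unavailable."""


class FixtureSpecError(BundlekitError):
    """A planted-MSA specification is self-contradictory."""
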