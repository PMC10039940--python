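"""Exception hierarchy.

All package errors derive from :class:`AmparkitError` so callers can catch
one base class at pipeline boundaries.
"""


class AmparkitError(Exception):
    """Base class for all amparkit errors."""


class ParseError(AmparkitError):
    """A structure or table file could not be parsed."""


class EmptyInputError(AmparkitError):
    """An input contained no usable records."""


class TopologyError(AmparkitError):
    """Trajectory and topology disagree (e.g. atom-count mismatch)."""


class FormatError(AmparkitError):
    """An input file is not in a readable format."""


class SelectionError(AmparkitError):
    """An atom/residue selection is empty, invalid or unresolvable."""


class CoverageError(AmparkitError):
    """A trajectory does not span the requested analysis window."""


class MixingError(AmparkitError):
    """Contact maps with inconsistent provenance were combined."""


class ComparisonError(AmparkitError):
    """Two maps being compared do not describe the same interface."""


class ParameterError(AmparkitError):
    """A parameter value is outside its valid domain."""


class DegenerateSelectionError(AmparkitError):
    """A superposition selection has fewer than 3 non-collinear atom pairs."""


class WindowError(AmparkitError):
    """An analysis window does not overlap the available data."""


class NoResponseError(AmparkitError):
    """A current trace shows no response above the noise floor."""


class FitError(AmparkitError):
    """A least-squares fit failed to converge."""
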