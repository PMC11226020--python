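"""Exception hierarchy for pamval.

Everything raised on bad user input derives from :class:`PamvalError` so
callers (and the CLI) can catch one base class.
"""


class PamvalError(Exception):
    """Base class for all pamval errors."""


class FormatError(PamvalError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(PamvalError):
    """A value violates a domain invariant (e.g. confidence outside [0, 1])."""


class MappingError(PamvalError):
    """A species is missing from a required mapping (SSC map, alias catalog)."""


class EmptyPoolError(PamvalError):
    """A sampling pool is empty (no eligible detections / no eligible time)."""


class UndefinedMetricError(PamvalError):
    """A metric has an empty denominator (e.g. precision of zero annotations)."""


class SSCAssignmentError(PamvalError):
    """The species-specific threshold rule needs a max-FP confidence that is missing."""


class PairingError(PamvalError):
    """Paired analysis units cannot be aligned between the two methods."""


class CapacityError(PamvalError):
    """A recording block cannot hold the number of non-overlapping segments requested."""
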