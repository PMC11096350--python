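"""Exception hierarchy shared across the pipeline."""


class HrvpcError(Exception):
    """Base class for all package errors."""


class ParseError(HrvpcError):
    """Malformed input file; message names the offending line."""


class ValidationError(HrvpcError):
    """Input violates a documented precondition or invariant."""


class InsufficientDataError(HrvpcError):
    """Series too short for the requested operation."""


class QualityError(HrvpcError):
    """Segment fails a quality gate (e.g. too many edited beats)."""


class NoBeatsError(HrvpcError):
    """QRS detection found no plausible beats."""


class CoverageError(HrvpcError):
    """Requested analysis window exceeds the available recording."""


class PipelineError(HrvpcError):
    """A pipeline stage failed; message carries stage provenance."""
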