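"""Exception hierarchy for the walkdist pipeline."""


class WalkdistError(Exception):
    """Base class for all walkdist errors."""


class FormatError(WalkdistError):
    """A file does not conform to the documented layout."""


class UnitError(WalkdistError):
    """A unit declaration is outside the supported set."""


class ValidationError(WalkdistError):
    """Data violates a documented invariant (monotonicity, length, finiteness)."""


class AlignmentError(WalkdistError):
    """Two per-sample structures that must be sample-aligned are not."""
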