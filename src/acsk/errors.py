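"""Exception hierarchy shared by all acsk modules."""


class AcskError(Exception):
    """Base class for all errors raised by acsk."""


class FormatError(AcskError):
    """A file does not conform to its declared format (FASTA, PHYLIP, Newick)."""


class ValidationError(AcskError):
    """Input data violates a documented precondition or invariant."""


class BoundsError(AcskError, IndexError):
    """A sequence or text position is out of range."""


class SizeError(AcskError):
    """An input exceeds the configured size cap of a quadratic oracle."""


class ParameterError(AcskError, ValueError):
    """A numeric parameter is outside its admissible range."""
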