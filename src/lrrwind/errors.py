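"""Exception hierarchy for lrrwind."""


class LrrWindError(Exception):
    """Base class for all lrrwind errors."""


class StructureFormatError(LrrWindError):
    """Raised when a structure file cannot be parsed as PDB or mmCIF."""


class ChainNotFoundError(LrrWindError, LookupError):
    """Raised when the requested chain is absent from the structure."""


class NumericalError(LrrWindError, ArithmeticError):
    """Raised when a geometric computation degenerates (zero tangent,
    rank-deficient frame projection, near-origin planar point, ...).

    The message names the offending residue/position.
    """
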