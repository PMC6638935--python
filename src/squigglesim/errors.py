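"""Exception hierarchy for squigglesim."""


class SquiggleSimError(Exception):
    """Base class for all squigglesim errors."""


class InvalidSequenceError(SquiggleSimError, ValueError):
    """Sequence contains characters outside the k-mer model alphabet."""


class LengthError(SquiggleSimError, ValueError):
    """An input series is too short for the requested operation."""


class ZeroVarianceError(SquiggleSimError, ValueError):
    """A constant signal cannot be z-normalized."""


class FormatError(SquiggleSimError, ValueError):
    """A file does not conform to the expected dialect."""


class ConfigError(SquiggleSimError, ValueError):
    """A simulation configuration is inconsistent or degenerate."""


class EmptyEnsembleError(SquiggleSimError, ValueError):
    """An operation that needs squiggles received none."""
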