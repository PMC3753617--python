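"""Exception hierarchy for mirduplex."""


class MirduplexError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(MirduplexError, ValueError):
    """Sequence contains characters outside the RNA alphabet after normalization."""


class StructureParseError(MirduplexError, ValueError):
    """Dot-bracket string is malformed; ``index`` points at the offending character."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (at index {index})")
        self.index = index


class NoLoopError(MirduplexError, ValueError):
    """Structure contains no hairpin loop (zero base pairs)."""


class NoStarError(MirduplexError, ValueError):
    """Candidate interval has no paired position, so no miRNA* can be derived."""


class ContractError(MirduplexError, ValueError):
    """An operation was called with inputs violating its contract."""


class TrainingError(MirduplexError, ValueError):
    """Training data cannot support model fitting (e.g. single-class labels)."""


class ModelLoadError(MirduplexError, IOError):
    """Model container is corrupted, truncated or of an incompatible version."""


class FingerprintMismatchError(MirduplexError, ValueError):
    """Model was trained against a different feature registry."""


class InputError(MirduplexError, ValueError):
    """User-supplied input files are unusable (empty, mismatched, malformed)."""
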