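"""Exception hierarchy.

Pipeline stages raise subclasses of :class:`TorsobaroError` so callers can
distinguish bad input (exit code 1) from processing failures (exit code 2).
"""


class TorsobaroError(Exception):
    """Base class for all package errors."""


class InputError(TorsobaroError):
    """Invalid user input: missing files, empty recordings, bad labels."""


class FormatError(InputError):
    """Malformed frame file (ragged rows, negative or non-finite values)."""


class DomainError(TorsobaroError):
    """Argument outside its admissible range (e.g. rotation beyond the grid)."""


class AlignmentError(TorsobaroError):
    """Symmetry alignment failed (e.g. image carries no imprint)."""


class DetectionError(TorsobaroError):
    """A landmark or structure could not be located."""


class FitError(TorsobaroError):
    """A regression or mask fit is underdetermined or degenerate."""


class UndefinedRatioError(TorsobaroError):
    """A ratio parameter hit a zero denominator."""


class SpecError(TorsobaroError):
    """Invalid phantom or study specification."""


class PipelineError(TorsobaroError):
    """Composite failure; carries the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
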