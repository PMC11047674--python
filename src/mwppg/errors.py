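"""Exception hierarchy for the mwppg pipeline."""


class MWPPGError(Exception):
    """Base class for all mwppg errors."""


class ConfigError(MWPPGError, ValueError):
    """Invalid configuration (simulation, model or training)."""


class ParseError(MWPPGError, ValueError):
    """A signal or labels file could not be parsed; names the offending line."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        self.path = path
        self.line_number = line_number
        where = f"{path}:" if path is not None else ""
        if line_number is not None:
            where += f"line {line_number}: "
        super().__init__(where + message)


class FormatError(ParseError):
    """The file layout does not match the four-column signal dialect."""


class ValidationError(MWPPGError, ValueError):
    """Data violates a semantic invariant (e.g. SBP <= DBP)."""


class SamplingError(MWPPGError, ValueError):
    """Sampling rate incompatible with the requested filter band."""


class DegenerateInputError(MWPPGError, ValueError):
    """Constant or otherwise degenerate input where variation is required."""


class LengthError(MWPPGError, ValueError):
    """Signal too short for the requested windowing."""


class ShapeError(MWPPGError, ValueError):
    """Array shapes inconsistent with the operation's contract."""


class SplitError(MWPPGError, ValueError):
    """Dataset cannot be partitioned as requested."""


class SampleSizeError(MWPPGError, ValueError):
    """Too few samples for the requested statistic."""


class DivergenceError(MWPPGError, RuntimeError):
    """Training produced non-finite loss."""
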