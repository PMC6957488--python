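"""Exception hierarchy.

Every error raised by the package derives from :class:`OxyflowError` so
callers (and the CLI) can map failures to exit codes without matching on
library-internal types.
"""


class OxyflowError(Exception):
    """Base class for all package errors."""


class ParameterError(OxyflowError, ValueError):
    """A scalar parameter is out of range or non-finite."""


class FormatError(OxyflowError, ValueError):
    """An input file violates the canonical long-format contract."""


class RangeError(OxyflowError, ValueError):
    """A requested window or length falls outside the data span."""


class DesignError(OxyflowError, ValueError):
    """Data do not match the declared study design (missing conditions,
    subject/condition mismatches)."""


class DegenerateSignalError(OxyflowError, ValueError):
    """A statistic is undefined on this input (zero template matches,
    constant series, too few complete observations)."""


class PipelineStageError(OxyflowError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
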