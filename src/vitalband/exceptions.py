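"""Exception types shared across the package."""


class VitalbandError(Exception):
    """Base class for all package-specific errors."""


class UndefinedRatioError(VitalbandError, ValueError):
    """Raised when the modulation ratio is undefined (zero or missing IR AC)."""


class DegenerateDataError(VitalbandError, ValueError):
    """Raised when a statistical test cannot be computed (e.g. all-zero
    paired differences under the Wilcoxon signed-rank test)."""


class DeviceLogError(VitalbandError, ValueError):
    """Raised on malformed device-log files.

    Attributes
    ----------
    line : int or None
        1-based line number of the offending row, when known.
    """

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
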