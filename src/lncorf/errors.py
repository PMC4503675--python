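"""Exception hierarchy shared across the package."""


class LncOrfError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LncOrfError):
    """A file violated the expected on-disk format."""


class UndefinedValueError(LncOrfError):
    """A statistic is undefined for the given input (e.g. empty sequence)."""


class InsufficientEvidenceError(LncOrfError):
    """Not enough observations to apply a decision rule."""
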