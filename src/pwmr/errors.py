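"""Exception hierarchy shared across the package."""


class PwmrError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PwmrError):
    """A configuration problem (missing column, bad mapping, bad preset)."""


class EmptyInputError(PwmrError):
    """An input table contained no usable rows."""


class DuplicateVariantError(PwmrError):
    """A variant identifier occurred more than once in one table."""


class EmptyOverlapError(PwmrError):
    """Two tables share no variants."""


class MissingLdError(PwmrError):
    """A candidate instrument is absent from the supplied LD matrix."""


class InvalidSampleSizeError(PwmrError):
    """Sample size too small for the requested statistic (n <= k + 1)."""


class DegenerateInstrumentError(PwmrError):
    """An instrument has a zero exposure effect; ratio undefined."""


class InsufficientInstrumentsError(PwmrError):
    """Too few instruments for the requested method."""


class CollinearityError(PwmrError):
    """The exposure design matrix is rank deficient."""
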