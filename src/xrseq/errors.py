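"""Exception types shared across the package."""


class XrseqError(Exception):
    """Base class for all errors raised by xrseq."""


class UndefinedRatioError(XrseqError):
    """A strand ratio is undefined because its denominator is zero."""
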