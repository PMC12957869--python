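"""Exception hierarchy.

``BcscreenError`` marks user-facing errors (bad input, bad parameters);
anything else escaping the API is an internal error.  The CLI maps the
two onto exit codes 1 and 2.
"""


class BcscreenError(Exception):
    """Base class for user-facing errors."""


class InvalidAlphabetError(BcscreenError):
    """A sequence contains characters outside A/C/G/T (or N where allowed)."""


class InsufficientPoolError(BcscreenError):
    """An operation requiring >= 2 barcodes received fewer."""


class PoolIntegrityError(BcscreenError):
    """A loaded pool violates its declared minimum distance or is malformed."""


class EmptySampleError(BcscreenError):
    """A sample with no positive counts cannot be converted to fractions."""


class MissingInputPoolError(BcscreenError):
    """No sample is flagged as an uninjected input pool."""


class SampleSheetError(BcscreenError):
    """Sample sheet fails schema or integrity validation."""
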