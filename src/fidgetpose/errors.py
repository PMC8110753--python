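"""Exception types raised by the pipeline."""


class FidgetposeError(Exception):
    """Base class for all package errors."""


class ParseError(FidgetposeError):
    """A keypoint file could not be parsed; the message names the file."""


class FormatError(FidgetposeError):
    """Parsed data violates the expected keypoint layout."""


class AmbiguousPersonError(FidgetposeError):
    """A frame contains more than one detected person and no person index
    was given to disambiguate."""


class UnusableSnippetError(FidgetposeError):
    """A snippet has too few confident keypoints to be normalized."""
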