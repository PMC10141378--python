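"""Exception hierarchy.

``VRSenseError`` is the base for everything the pipeline raises on bad
inputs or misuse; the CLI maps it to exit status 1 and anything else to 2.
"""


class VRSenseError(Exception):
    """Base class for all errors raised by vrsense."""


class FormatError(VRSenseError):
    """A file does not conform to the expected layout (missing column,
    unknown class label, unparsable filename)."""


class ValidationError(VRSenseError):
    """Data violates a contract (duplicate timestamps, value out of range,
    ragged table, unfitted model)."""
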