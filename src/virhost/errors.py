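"""Exception hierarchy.

``FormatError`` means the bytes on disk could not be parsed; ``ValidationError``
means they parsed but violate an invariant (unknown node id, negative count,
duplicate key); ``UndefinedMetricError`` means a statistic has no defined value
for the given input (all-zero counts, a single placed read, a constant vector).
The CLI maps all three to exit code 2.
"""


class VirhostError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VirhostError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(VirhostError):
    """Parsed data violates a structural invariant."""


class UndefinedMetricError(VirhostError):
    """A metric is mathematically undefined for the given input."""
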