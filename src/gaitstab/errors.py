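"""Exception hierarchy.

Every error raised by gaitstab derives from :class:`GaitStabError`, so callers
(and the CLI) can distinguish user/input problems from genuine bugs.
"""


class GaitStabError(Exception):
    """Base class for all gaitstab errors."""


class ParameterError(GaitStabError, ValueError):
    """An argument is out of its documented domain (non-positive rate, bad bound...)."""


class SegmentationError(GaitStabError, ValueError):
    """Gait-event detection or cycle extraction cannot produce the requested cycles."""


class NormalizationError(GaitStabError, ValueError):
    """A normalization step is degenerate (all-zero envelope, constant column...)."""


class SchemaError(GaitStabError, ValueError):
    """An input table/file does not match the expected column schema."""
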