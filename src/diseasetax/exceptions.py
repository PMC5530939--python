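"""Exception hierarchy shared across the package.

All errors raised on bad scientific input derive from
:class:`DiseasetaxError`, so callers (and the CLI) can catch one base class.
"""


class DiseasetaxError(Exception):
    """Base class for all diseasetax errors."""


class ParseError(DiseasetaxError):
    """A file could not be parsed; the message names the offending line."""


class StructuralError(DiseasetaxError):
    """A hierarchy violates a structural invariant (cycle, dangling edge)."""


class DomainError(DiseasetaxError):
    """An operation was applied to input outside its domain
    (unknown term, empty gene set, missing citation entry, ...)."""


class LookupError_(DiseasetaxError):
    """A term or name was not found where one is required."""


class SizeError(DiseasetaxError):
    """A subnetwork did not meet a size requirement."""

    def __init__(self, message: str, count: int):
        super().__init__(message)
        self.count = count


class ConfigError(DiseasetaxError):
    """A synthetic-data configuration is self-inconsistent."""
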