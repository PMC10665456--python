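"""Exception hierarchy shared across the package.

Each class carries a distinct process exit code so the command-line
front end can map error classes to shell-visible statuses.
"""


class EndospectError(Exception):
    """Base class for all endospect errors."""

    exit_code = 1


class DomainError(EndospectError, ValueError):
    """A value lies outside its physically or mathematically valid domain."""

    exit_code = 2


class ShapeError(EndospectError, ValueError):
    """Array shapes or counts are inconsistent."""

    exit_code = 3


class FormatError(EndospectError, ValueError):
    """A file does not conform to its declared on-disk format."""

    exit_code = 4


class StateError(EndospectError, RuntimeError):
    """An operation was invoked before the artifacts it needs were fitted."""

    exit_code = 5


class PairingError(ShapeError):
    """Paired image sets have mismatched lengths."""

    exit_code = 6


class EmptyContentError(DomainError):
    """Border trimming removed the entire image."""

    exit_code = 7
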