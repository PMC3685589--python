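"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`ConfigError` -> 2,
:class:`NumericalError` -> 3.
"""


class HHCableError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HHCableError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(HHCableError, ValueError):
    """A configuration file or flag set is malformed or inconsistent."""


class NumericalError(HHCableError, RuntimeError):
    """The integrator produced a non-finite state (diverged)."""
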