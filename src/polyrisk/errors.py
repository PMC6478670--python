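"""Exception hierarchy.

``PolyriskError`` is the base for everything raised deliberately by this
package; the CLI maps it to exit code 2 (validation / domain errors) while
I/O problems map to exit code 3.
"""


class PolyriskError(Exception):
    """Base class for all polyrisk errors."""


class ConfigParseError(PolyriskError):
    """A configuration file could not be parsed (names the offending row/key)."""


class ValidationError(PolyriskError):
    """A domain invariant was violated (names the factor and the rule)."""


class DomainError(PolyriskError, ValueError):
    """A numeric argument is outside its mathematical domain."""
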