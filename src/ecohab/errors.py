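"""Exception hierarchy shared across the package.

All data-level failures derive from :class:`EcoHabError` so the command-line
layer can map them to a dedicated exit code, distinct from usage errors and
internal faults.
"""


class EcoHabError(Exception):
    """Base class for all data/validation errors raised by ecohab."""


class ParseError(EcoHabError):
    """A text input (raw log, registry, config) could not be parsed."""


class ValidationError(EcoHabError):
    """Parsed data violates a structural invariant."""


class ConfigError(EcoHabError):
    """An experiment/phase/run configuration is inconsistent."""
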