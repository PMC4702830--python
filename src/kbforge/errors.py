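"""Exception hierarchy.

All library errors derive from :class:`KbforgeError` so callers (and the CLI)
can catch one base class. ``DomainError`` additionally derives from
``ValueError`` because it signals out-of-bounds numeric arguments.
"""


class KbforgeError(Exception):
    """Base class for all kbforge errors."""


class FormatError(KbforgeError):
    """Malformed input file (missing column, duplicate id, unparseable)."""


class UsageError(KbforgeError):
    """Operation invoked with arguments that make it meaningless."""


class IntegrityError(KbforgeError):
    """Internally inconsistent objects passed together (e.g. KB not derived
    from the given index, span outside its document)."""


class ConfigurationError(KbforgeError):
    """Components wired together that do not cover each other (e.g. an index
    built without the dictionary being reported on)."""


class DomainError(KbforgeError, ValueError):
    """Numeric argument outside its mathematical domain."""
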