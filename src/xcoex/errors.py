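"""Exception hierarchy.

Validation problems (bad file content, bad configuration, inconsistent
cross-references) are distinguished from runtime failures so the CLI can map
them to distinct exit codes.
"""


class XcoexError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XcoexError):
    """A file does not conform to its documented format."""


class ConfigError(XcoexError):
    """A configuration value is missing, unknown, or out of range."""


class CrossReferenceError(XcoexError):
    """Two inputs that must agree (e.g. regions vs. annotations) do not."""
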