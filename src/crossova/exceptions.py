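"""Exception types shared across the package."""


class CrossovaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrossovaError, ValueError):
    """Invalid configuration (bad proportions, duplicate ids, unknown keys...)."""


class EmptyResultError(CrossovaError, ValueError):
    """An operation removed every record; returned explicitly, never silently."""


class ParseError(CrossovaError, ValueError):
    """A file on disk could not be parsed; message carries file and line."""
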