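"""Exception types shared across the pipeline."""


class SlicegliaError(Exception):
    """Base class for all package errors."""


class FormatError(SlicegliaError, ValueError):
    """A file does not conform to the expected dialect."""


class IdentifierError(SlicegliaError, ValueError):
    """Duplicate or inconsistent gene/observation identifiers."""


class ConfigError(SlicegliaError, ValueError):
    """Invalid parameter combination passed to an operation."""
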