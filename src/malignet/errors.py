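"""Exception types shared across the pipeline stages."""


class MalignetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MalignetError):
    """A simulation or pipeline configuration field is invalid."""


class InputError(MalignetError):
    """User-supplied data violates a documented precondition."""
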