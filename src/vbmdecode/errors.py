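"""Exception hierarchy shared across the pipeline."""


class VBMDecodeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VBMDecodeError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ShapeMismatchError(VBMDecodeError, ValueError):
    """Grids or feature dimensions do not agree."""


class DegenerateInputError(VBMDecodeError, ValueError):
    """Input without the variation the operation requires (constant map,
    single-class labels, zero-variance classifier, ...)."""
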