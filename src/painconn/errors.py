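"""Exception hierarchy shared across the pipeline."""


class PainconnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PainconnError):
    """Invalid configuration value; the message names the offending field."""


class GenerationError(PainconnError):
    """Synthetic-data generation could not satisfy its contract."""


class FormatError(PainconnError):
    """An input file violated its schema; the message names file and rule."""


class ModelError(PainconnError):
    """A regression fit is degenerate (rank deficiency, too few subjects)."""
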