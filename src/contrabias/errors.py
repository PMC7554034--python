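"""Exception types shared across the pipeline."""


class ContrabiasError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ContrabiasError, ValueError):
    """Invalid task or observer configuration."""


class InputError(ContrabiasError, ValueError):
    """Invalid data passed to an operation (bad frequencies, indices, ...)."""


class SchemaError(ContrabiasError, ValueError):
    """A trial log does not conform to the CSV trial-log schema.

    Carries an ``errors`` list of itemized, line-referenced problems.
    """

    def __init__(self, message, errors=None):
        super().__init__(message)
        self.errors = list(errors or [])


class StatsError(ContrabiasError, ValueError):
    """A model cannot be fit (degenerate data, missing levels, ...)."""


class NoFitError(ContrabiasError, ValueError):
    """Observed moments fall outside the envelope achievable on the grid.

    Carries the achievable ``envelope`` as a dict of (min, max) per moment.
    """

    def __init__(self, message, envelope=None):
        super().__init__(message)
        self.envelope = envelope or {}
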