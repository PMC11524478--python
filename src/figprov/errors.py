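"""Exception hierarchy shared across the pipeline."""


class FigprovError(Exception):
    """Base class for all figprov errors."""


class IngestError(FigprovError):
    """A document or figure could not be read (bad PDF, missing file...)."""


class ConfigurationError(FigprovError):
    """A backend was requested without the resources it needs."""


class ValidationError(FigprovError):
    """Inputs violate a contract (unknown ids, overlapping groups...)."""
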