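"""Exception hierarchy for cpetwave."""


class CpetwaveError(Exception):
    """Base class for all cpetwave errors."""


class FormatError(CpetwaveError):
    """A file does not conform to the expected layout (missing column, bad header)."""


class DataError(CpetwaveError):
    """Input data violates a content requirement (no finite samples, unknown label, ...)."""


class DecompositionError(CpetwaveError):
    """A signal cannot support the requested wavelet decomposition depth."""


class FitError(CpetwaveError):
    """A classifier cannot be trained on the given inputs."""


class SchemaError(CpetwaveError):
    """Feature columns do not match what a fitted model was trained on."""


class ConfigError(CpetwaveError):
    """An invalid configuration value."""
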